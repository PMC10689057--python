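"""Universal genetic code lookup shared by the simulator and Ka/Ks code.

Built once from Biopython's standard DNA codon table; stop codons map to
``"*"``. Only the universal code is supported (a code-table parameter is
reserved for the future).
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List

from Bio.Data.CodonTable import standard_dna_table

ALL_CODONS: List[str] = ["".join(c) for c in product("ACGT", repeat=3)]

AA: Dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    AA[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS
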