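"""Locate the 9-mer binding core of a peptide by sliding-window scanning.

Uses the bundled reference table of solved HLA-DR/peptide complexes: a PSSM
rewarding the experimentally determined core residues of the 1BX2 complex
(myelin basic protein peptide on DRB1*15:01) must find that core exactly.
"""

import numpy as np

from pocketpan import PSSM, load_complex_records, scan_peptide
from pocketpan.alphabet import AA_INDEX

records = {r.pdb_id: r for r in load_complex_records()}
rec = records["1BX2"]

matrix = np.zeros((9, 20))
for pocket, aa in enumerate(rec.core):
    matrix[pocket, AA_INDEX[aa]] = 2.0
pssm = PSSM(rec.allele, matrix, frozenset())

result = scan_peptide(pssm, rec.peptide)
print(f"peptide {rec.peptide} ({rec.allele}, structure {rec.pdb_id})")
print("window scores:", " ".join(f"{s:.1f}" for s in result.window_scores))
print(f"predicted core: {result.core} at offset {result.core_start}")
print(f"known core:     {rec.core} at offset {rec.core_start}")
print()
print(
    "The maximal window (score 18.0: nine residues x 2.0 each) sits at the "
    "crystallographic core offset; every other window scores lower because "
    "it misaligns the anchor residues."
)
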