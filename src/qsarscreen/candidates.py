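"""Bundled reference panel of 27 kinase-inhibitor candidates.

A small worked-example dataset of quinazoline-type EGFR inhibitors (rows
1-18), PI3Kp110beta inhibitors (rows 19-24), and dual EGFR/PI3K
inhibitors (rows 25-27), each with its SMILES, predicted logBB, predicted
-pIC50 per target, docking score, and ligand efficiency.  The panel
exercises the multi-target selection cascade end to end: applying the
default screening thresholds to these predictions keeps 18 EGFR, 6 PI3K,
and 3 dual candidates.

Dual-target rows carry a -pIC50 and docking score for each target
(``pic50_egfr`` / ``pic50_pi3k``); single-target rows carry the value
only for their own target.
"""

from __future__ import annotations

import pandas as pd

# columns: mol_id, zinc_id, target, smiles, logbb, pic50_egfr, pic50_pi3k,
#          score_egfr, score_pi3k, ligand_efficiency
_PANEL = [
    (1, "ZINC132618", "egfr", "Clc1cc(Cl)cc(Nc2ncnc3ccccc23)c1", 0.221, 7.121, None, 54.66, None, 3.356),
    (2, "ZINC955717", "egfr", "Fc1ccc(Nc2ncnc3ccc(Br)cc23)cc1Cl", 0.221, 7.253, None, 64.7, None, 3.498),
    (3, "ZINC99087", "egfr", "Fc1ccc(Nc2ncnc3ccc(Br)cc23)cc1", 0.229, 7.397, None, 65.51, None, 2.786),
    (4, "ZINC65031", "egfr", "Oc1ccc(Nc2ncnc3ccccc23)cc1", 0.216, 7.1, None, 56.24, None, 3.217),
    (5, "ZINC949364", "egfr", "Brc1ccc2ncnc(Nc3cccc4ccccc34)c2c1", 0.225, 7.243, None, 66.25, None, 3.551),
    (6, "ZINC4710712", "egfr", "C(Nc1ccccc1-c2nnn[nH]2)c3cccnc3", 0.27, 7.381, None, 62.22, None, 2.967),
    (7, "ZINC2664933", "egfr", "COc1ccc(CNc2ncnc3sc(cc23)-c4ccccc4)cc1", 0.343, 7.299, None, 77.73, None, 3.206),
    (8, "ZINC71920558", "egfr", "Oc1ccc(Nc2ncnc3ccsc23)cc1CN4CCOCC4", 0.274, 7.131, None, 70.63, None, 3.871),
    (9, "ZINC13863969", "egfr", "C[C@@H](Nc1ncnc2ccccc12)c3ccc4ccccc4c3", 0.466, 7.196, None, 79.07, None, 3.438),
    (10, "ZINC9074069", "egfr", "CCCCc1ccc(Nc2nc(Nc3ccc(F)cc3)c4nccnc4n2)cc1", 0.329, 7.46, None, 80.78, None, 2.786),
    (11, "ZINC13010674", "egfr", "Fc1ccc(Nc2nc(NCCN3CCOCC3)nc4nccnc24)cc1", 0.203, 7.184, None, 75.64, None, 3.465),
    (12, "ZINC22735958", "egfr", "OCCN1CCN(CC1)c2nc(Nc3ccccc3)c4nccnc4n2", 0.282, 7.236, None, 74.87, None, 3.652),
    (13, "ZINC117048", "egfr", "COc1cccc(Nc2ncnc3cc(sc23)-c4ccccc4)c1", 0.571, 7.401, None, 77.21, None, 3.217),
    (14, "ZINC955103", "egfr", "Clc1cccc(Nc2ncnc3ccc(I)cc23)c1", 0.282, 7.207, None, 63.2, None, 2.893),
    (15, "ZINC122234", "egfr", "Cc1cccc(Nc2ncnc3ccc(Br)cc23)c1", 0.296, 7.379, None, 64.5, None, 3.365),
    (16, "ZINC140100", "egfr", "Brc1ccc2ncnc(Nc3ccccc3)c2c1", 0.285, 7.14, None, 62.18, None, 3.762),
    (17, "ZINC144105", "egfr", "Brc1ccc(Nc2ncnc3ccccc23)cc1", 0.216, 7.1, None, 58.15, None, 3.994),
    (18, "ZINC48331888", "egfr", "CCc1cccc(Nc2ncnc3cc(Cl)ccc23)c1", 0.22, 7.16, None, 66.02, None, 2.634),
    (19, "ZINC20729292", "pi3k", "CCCCN1CCCc2cc(CN(CCN3CCOCC3)C(=S)Nc3cc(F)cc(F)c3)ccc21", 0.152, None, 6.797, None, -146.243, 4.228),
    (20, "ZINC36307506", "pi3k", "C=CCC[C@@H](O)CN(Cc1ccco1)Cc1c(-c2ccccc2)nn(C)c1Oc1ccc(F)cc1", 0.056, None, 6.763, None, -145.661, 4.12),
    (21, "ZINC9873787", "pi3k", "CN(Cc1ccc(N2CCOCC2)cc1)C(=O)c1cc(-c2ccccc2)c(N2CCOCC2)s1", 0.049, None, 6.774, None, -145.661, 3.593),
    (22, "ZINC977288", "pi3k", "C=CCn1c(C)c(C=C2C(=O)OC3(CCCCC3)OC2=O)c2ccccc21", 0.162, None, 6.883, None, -115.83, 3.557),
    (23, "ZINC68202727", "pi3k", "CCc1c(O)cc(O)c(C(=O)c2ccc(OCCN3CCOCC3)c(OC)c2)c1CC(=O)N(CCOC)CCOC", 0.0097, None, 6.86313, None, -153.535, 3.534),
    (24, "ZINC218287337", "pi3k", "COC(=O)C[C@@H](c1oc(CN2CCCCC2)cc(=O)c1O)c1c(F)cccc1Cl", 0.043, None, 6.913, None, -167.605, 4.061),
    (25, "ZINC27439698", "dual", "Fc1ccc(Nc2ncnc3cc(OCCCN4CCOCC4)c(NC(=O)C=C)cc23)cc1Cl", -0.056, 8.348, 6.22, 85.04, -141.013, 2.501),
    (26, "ZINC20615563", "dual", "Oc1c(Cl)cc(Cl)c2ccc(NN=C3c4cc(OCC=C)ccc4-c5ccc(OCC=C)cc35)nc12", -0.122, 6.42, 6.696, 78.9, -120.816, 2.744),
    (27, "ZINC1488208", "dual", "Brc1cccc(Nc2ncnc3ccc(NC(=O)C=C)cc23)c1", -0.0718, 8.796, 5.636, 68.3, -98.6951, 2.972),
]

_COLUMNS = ["mol_id", "zinc_id", "target", "smiles", "logbb",
            "pic50_egfr", "pic50_pi3k", "score_egfr", "score_pi3k",
            "ligand_efficiency"]


def reference_panel() -> pd.DataFrame:
    """The 27-candidate reference panel as a DataFrame (one row per molecule)."""
    return pd.DataFrame(_PANEL, columns=_COLUMNS)
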