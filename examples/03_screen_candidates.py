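"""The multi-target selection cascade on the bundled 27-candidate panel.

Each candidate carries predicted logBB (brain/blood partitioning) and
predicted -pIC50 per target.  Selection keeps: EGFR candidates with
logBB >= 0.2 and -pIC50 >= 7; PI3Kp110beta candidates with logBB >= 0
and -pIC50 >= 6.5; dual candidates with logBB >= -0.2 and a product of
the two targets' spIC50 values of at least 0.1.
"""

import qsarscreen as qs

panel = qs.reference_panel()
for mode in ("egfr", "pi3k", "dual"):
    sub = panel[panel.target == mode].rename(columns={"mol_id": "id"})
    report = qs.select_candidates(sub, mode)
    print(f"{mode:>4} mode: kept {len(report.kept_ids)}/{len(sub)}")

row = panel[panel.mol_id == 25].iloc[0]
score = qs.dual_score(row.pic50_egfr, row.pic50_pi3k)
print(f"\nmolecule 25 dual score: spIC50(EGFR) x spIC50(PI3K) "
      f"= {qs.pic50_to_sp(row.pic50_egfr):.3f} x {qs.pic50_to_sp(row.pic50_pi3k):.3f} "
      f"= {score:.4f} (bound 0.1)")

ann = qs.annotate(row.smiles, docking_score=row.score_egfr)
print(f"molecule 25 annotation: MW {ann.mw:.1f} Da, {ann.heavy_atoms} heavy atoms, "
      f"{ann.lipinski_violations} Lipinski violations, "
      f"ligand efficiency {ann.ligand_efficiency:.2f}")
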