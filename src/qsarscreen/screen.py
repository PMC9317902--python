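"""Virtual-screening filter cascade and candidate annotation.

Implements the multi-target selection logic: PAINS substructure removal,
per-target potency/permeation thresholds (including the dual-target
spIC50-product rule), drug-likeness annotation, and a linear
score-vs-activity calibration utility.  The full pipeline
(:func:`screen_library`) runs: curate -> fingerprint -> predict (+AD) ->
PAINS filter -> threshold selection -> annotate, and every rejection
carries the name of the rule that removed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from scipy import stats

from .chem import MoleculeRecord, canonicalize, fingerprint, pic50_to_sp
from .qsar import QsarModel, applicability_domain, _predict_bits

__all__ = [
    "TargetThresholds", "DualThresholds", "ScreeningThresholds",
    "CandidateAnnotation", "SelectionReport", "CalibrationFit",
    "pains_filter", "select_candidates", "annotate", "calibrate_scores",
    "screen_library", "DEFAULT_THRESHOLDS",
]


@dataclass(frozen=True)
class TargetThresholds:
    """Single-target selection bounds (both inclusive)."""

    logbb_min: float
    pic50_min: float


@dataclass(frozen=True)
class DualThresholds:
    """Dual-target bounds: spIC50 product and permeation floor (inclusive)."""

    logbb_min: float = -0.2
    sp_product_min: float = 0.1


@dataclass(frozen=True)
class ScreeningThresholds:
    """Per-mode screening cutoffs.

    Defaults: EGFR keeps logBB >= 0.2 and -pIC50 >= 7; PI3Kp110beta keeps
    logBB >= 0 and -pIC50 >= 6.5; dual targeting keeps logBB >= -0.2 and
    spIC50(EGFR) x spIC50(PI3K) >= 0.1.
    """

    egfr: TargetThresholds = TargetThresholds(logbb_min=0.2, pic50_min=7.0)
    pi3k: TargetThresholds = TargetThresholds(logbb_min=0.0, pic50_min=6.5)
    dual: DualThresholds = DualThresholds()

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningThresholds":
        kwargs = {}
        if "egfr" in d:
            kwargs["egfr"] = TargetThresholds(**d["egfr"])
        if "pi3k" in d:
            kwargs["pi3k"] = TargetThresholds(**d["pi3k"])
        if "dual" in d:
            kwargs["dual"] = DualThresholds(**d["dual"])
        return cls(**kwargs)


DEFAULT_THRESHOLDS = ScreeningThresholds()


@dataclass
class CandidateAnnotation:
    """Drug-likeness summary of one candidate molecule."""

    id: str
    mw: float
    heavy_atoms: int
    lipinski_violations: int
    pains_flagged: bool
    pains_family: str | None = None
    ligand_efficiency: float | None = None


@dataclass
class SelectionReport:
    """Kept/rejected partition of a screened set, with the failing rule per rejection."""

    mode: str
    kept_ids: list[str]
    rejections: dict[str, str]          # id -> name of the first failing rule
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {"kept": len(self.kept_ids),
                           "rejected": len(self.rejections)}


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares line of activity against docking score."""

    slope: float
    intercept: float
    r2: float
    n: int


# ---------------------------------------------------------------------------
# PAINS

_pains_catalog: FilterCatalog | None = None


def _pains() -> FilterCatalog:
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalogParams()
        for fam in (FilterCatalogParams.FilterCatalogs.PAINS_A,
                    FilterCatalogParams.FilterCatalogs.PAINS_B,
                    FilterCatalogParams.FilterCatalogs.PAINS_C):
            params.AddCatalog(fam)
        _pains_catalog = FilterCatalog(params)
    return _pains_catalog


def pains_match(smiles: str) -> str | None:
    """Name of the first matching PAINS alert (families A+B+C), or None."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return "unparsable"
    entry = _pains().GetFirstMatch(mol)
    return entry.GetDescription() if entry is not None else None


def pains_filter(mols: list[MoleculeRecord]) -> tuple[list[MoleculeRecord],
                                                      list[tuple[MoleculeRecord, str]]]:
    """Split molecules into (kept, flagged-with-alert-family), preserving order."""
    kept: list[MoleculeRecord] = []
    flagged: list[tuple[MoleculeRecord, str]] = []
    for rec in mols:
        family = pains_match(rec.smiles_canonical)
        if family is None:
            kept.append(rec)
        else:
            flagged.append((rec, family))
    return kept, flagged


# ---------------------------------------------------------------------------
# threshold selection


def _required_columns(mode: str) -> list[str]:
    if mode == "egfr":
        return ["logbb", "pic50_egfr"]
    if mode == "pi3k":
        return ["logbb", "pic50_pi3k"]
    if mode == "dual":
        return ["logbb", "pic50_egfr", "pic50_pi3k"]
    raise ValueError(f"unknown screening mode {mode!r}")


def dual_score(pic50_egfr: float, pic50_pi3k: float) -> float:
    """Product of the two targets' spIC50 values (symmetric in the targets)."""
    return pic50_to_sp(pic50_egfr) * pic50_to_sp(pic50_pi3k)


def select_candidates(predictions: pd.DataFrame, mode: str,
                      thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS,
                      ) -> SelectionReport:
    """Apply the per-mode selection thresholds to a table of predictions.

    ``predictions`` needs an ``id`` column plus ``logbb`` and the
    per-target ``pic50_egfr`` / ``pic50_pi3k`` columns the mode requires.
    All comparisons are inclusive (>=); the first failing rule, checked in
    the order logBB then potency, names each rejection.
    """
    for col in ["id"] + _required_columns(mode):
        if col not in predictions.columns:
            raise ValueError(f"predictions table is missing column {col!r}"
                             f" (required for mode {mode!r})")
    kept: list[str] = []
    rejections: dict[str, str] = {}
    for row in predictions.itertuples():
        rid = str(row.id)
        if mode == "dual":
            t = thresholds.dual
            if not row.logbb >= t.logbb_min:
                rejections[rid] = "logbb_min"
            elif not dual_score(row.pic50_egfr, row.pic50_pi3k) >= t.sp_product_min:
                rejections[rid] = "sp_product_min"
            else:
                kept.append(rid)
        else:
            t = thresholds.egfr if mode == "egfr" else thresholds.pi3k
            pic50 = row.pic50_egfr if mode == "egfr" else row.pic50_pi3k
            if not row.logbb >= t.logbb_min:
                rejections[rid] = "logbb_min"
            elif not pic50 >= t.pic50_min:
                rejections[rid] = "pic50_min"
            else:
                kept.append(rid)
    return SelectionReport(mode=mode, kept_ids=kept, rejections=rejections)


# ---------------------------------------------------------------------------
# annotation


def annotate(mol: MoleculeRecord | str,
             docking_score: float | None = None) -> CandidateAnnotation:
    """Drug-likeness annotation: average-isotope MW, heavy atoms, Lipinski count.

    Lipinski violations count MW > 500, cLogP > 5, H-bond donors > 5, and
    acceptors > 10.  Ligand efficiency is |docking score| / heavy atoms
    when a score is supplied (absolute value so that both negative-better
    and positive-better scoring conventions give positive efficiencies).
    """
    if isinstance(mol, MoleculeRecord):
        mol_id, smiles = mol.id, mol.smiles_canonical
    else:
        mol_id, smiles = "", mol
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    heavy = m.GetNumHeavyAtoms()
    violations = sum([
        Descriptors.MolWt(m) > 500,
        Crippen.MolLogP(m) > 5,
        Lipinski.NumHDonors(m) > 5,
        Lipinski.NumHAcceptors(m) > 10,
    ])
    le = abs(docking_score) / heavy if docking_score is not None else None
    return CandidateAnnotation(
        id=mol_id,
        mw=float(Descriptors.MolWt(m)),
        heavy_atoms=heavy,
        lipinski_violations=int(violations),
        pains_flagged=pains_match(smiles) is not None,
        pains_family=pains_match(smiles),
        ligand_efficiency=le,
    )


# ---------------------------------------------------------------------------
# score calibration


def calibrate_scores(pairs: list[tuple[float, float]]) -> CalibrationFit:
    """Least-squares line of activity (-pIC50) against docking score.

    Requires at least 3 points and non-constant scores; r^2 is the squared
    Pearson correlation.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (score, activity) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("docking scores are degenerate (all equal)")
    fit = stats.linregress(x, y)
    return CalibrationFit(slope=float(fit.slope), intercept=float(fit.intercept),
                          r2=float(fit.rvalue ** 2), n=len(pairs))


# ---------------------------------------------------------------------------
# end-to-end library screen


_MODE_ENDPOINTS = {"egfr": ["egfr"], "pi3k": ["pi3k"], "dual": ["egfr", "pi3k"]}


def screen_library(library: list[tuple[str, str]],
                   models: dict[str, QsarModel], mode: str,
                   thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS,
                   ad_threshold: float = 0.7, ad_rule: str = "distance",
                   blocklist: set[str] | None = None,
                   ) -> tuple[SelectionReport, pd.DataFrame]:
    """Screen a SMILES library end to end.

    ``library`` is a list of (id, smiles); ``models`` maps endpoint names
    ('egfr', 'pi3k', 'bbb') to fitted models — the mode determines which
    are required ('bbb' always is).  Stages run in a fixed order: curate,
    fingerprint + predict with AD, PAINS filter, threshold selection,
    annotate.  Out-of-domain or PAINS-flagged molecules are carried
    through prediction but rejected at the selection stage with rules
    'ad' and 'pains'; an optional blocklist of ids or canonical SMILES
    rejects with rule 'blocklist'.  Returns the selection report and a
    per-molecule annotation table.
    """
    required = _MODE_ENDPOINTS.get(mode)
    if required is None:
        raise ValueError(f"unknown screening mode {mode!r}")
    for ep in required + ["bbb"]:
        if ep not in models:
            raise ValueError(f"mode {mode!r} requires a {ep!r} model")
    blocklist = blocklist or set()

    rows = []
    for mol_id, smiles in library:
        row: dict = {"id": str(mol_id), "smiles_raw": smiles}
        canon = canonicalize(smiles)
        row["smiles"] = canon
        if canon is None:
            row["stage_fail"] = "parse"
            rows.append(row)
            continue
        in_domain_all = True
        nn_sims = []
        for ep in required + ["bbb"]:
            model = models[ep]
            fp = fingerprint(canon, model.scheme, model.nbits)
            verdict = applicability_domain(fp.bits, model, ad_threshold, ad_rule)
            pred = float(_predict_bits(model, fp.bits[None, :])[0])
            in_domain_all &= verdict.in_domain
            nn_sims.append(verdict.nn_similarity)
            if ep == "bbb":
                row["logbb"] = pred
            else:
                # target models predict spIC50; thresholds speak -pIC50
                sp = float(np.clip(pred, 0.0, 1.0))
                row[f"sp_{ep}"] = sp
                row[f"pic50_{ep}"] = 5.0 + 4.0 * sp
        row["ad_flag"] = not in_domain_all
        row["nn_similarity"] = float(min(nn_sims))
        row["pains_family"] = pains_match(canon)
        row["pains_flag"] = row["pains_family"] is not None
        row["blocked"] = str(mol_id) in blocklist or canon in blocklist
        rows.append(row)
    table = pd.DataFrame(rows)

    kept: list[str] = []
    rejections: dict[str, str] = {}
    selectable = []
    for row in rows:
        rid = row["id"]
        if row.get("stage_fail") == "parse":
            rejections[rid] = "parse"
        elif row["blocked"]:
            rejections[rid] = "blocklist"
        elif row["ad_flag"]:
            rejections[rid] = "ad"
        elif row["pains_flag"]:
            rejections[rid] = "pains"
        else:
            selectable.append(row)
    if selectable:
        sub = pd.DataFrame(selectable)
        report = select_candidates(sub, mode, thresholds)
        kept = report.kept_ids
        rejections.update(report.rejections)
    final = SelectionReport(mode=mode, kept_ids=kept, rejections=rejections)

    # annotation columns for the report table
    if not table.empty:
        ann_rows = []
        for row in rows:
            if row.get("smiles"):
                a = annotate(row["smiles"])
                ann_rows.append({"id": row["id"], "mw": a.mw,
                                 "heavy_atoms": a.heavy_atoms,
                                 "lipinski_violations": a.lipinski_violations})
            else:
                ann_rows.append({"id": row["id"], "mw": np.nan,
                                 "heavy_atoms": np.nan,
                                 "lipinski_violations": np.nan})
        table = table.merge(pd.DataFrame(ann_rows), on="id")
        table["kept"] = table["id"].isin(set(kept))
        table["rejection_rule"] = table["id"].map(rejections)
    return final, table
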