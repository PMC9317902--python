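"""Molecule curation, activity scaling, fingerprinting, and data partitioning.

This module turns raw (id, SMILES, endpoint, value) activity tables into
clean, numerically encoded datasets:

* structures are reduced to their largest fragment (salt stripping) and
  canonicalized; duplicates sharing a canonical SMILES are merged;
* IC50 values in nM are mapped onto the unit interval by a censored
  logarithmic scale (spIC50), with the equivalent -pIC50 representation
  available through exact algebraic conversions;
* molecules are encoded as hashed binary substructure fingerprints
  (atom-pair by default, Morgan as an alternative);
* curated datasets are split into a 75% training / 25% independent
  validation partition by seeded random sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

VALID_NBITS = (256, 512, 1024)
VALID_SCHEMES = ("atompair", "morgan")

# censoring bounds of the spIC50 scale, in nM
IC50_LOWER_NM = 1.0
IC50_UPPER_NM = 10_000.0


class CurationError(ValueError):
    """Raised when curation produces an empty or inconsistent dataset."""


class ActivityKind(str, Enum):
    ic50_nM = "ic50_nM"
    sp_ic50 = "sp_ic50"
    pic50 = "pic50"
    logBB = "logBB"


@dataclass(frozen=True)
class ActivityValue:
    """A single measured or derived activity.

    ``ic50_nM`` is a positive concentration in nM, ``sp_ic50`` the scaled
    potency in [0, 1], ``pic50`` the negative log-molar potency in [5, 9],
    and ``logBB`` the log10 brain/blood concentration ratio.
    """

    kind: ActivityKind
    value: float

    def __post_init__(self) -> None:
        v = self.value
        if not math.isfinite(v):
            raise ValueError(f"non-finite activity value: {v!r}")
        if self.kind == ActivityKind.ic50_nM and v <= 0:
            raise ValueError(f"IC50 must be positive, got {v}")
        if self.kind == ActivityKind.sp_ic50 and not 0.0 <= v <= 1.0:
            raise ValueError(f"spIC50 must lie in [0, 1], got {v}")
        if self.kind == ActivityKind.pic50 and not 5.0 <= v <= 9.0 + 1e-12:
            raise ValueError(f"-pIC50 must lie in [5, 9], got {v}")


@dataclass
class MoleculeRecord:
    """One curated compound: canonical structure plus per-endpoint activities."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    activities: dict[str, ActivityValue] = field(default_factory=dict)


@dataclass(frozen=True)
class Fingerprint:
    """Folded binary substructure vector for one molecule."""

    scheme: str
    nbits: int
    bits: np.ndarray  # uint8 vector of length nbits

    def __post_init__(self) -> None:
        if len(self.bits) != self.nbits:
            raise ValueError("bit vector length does not match nbits")


@dataclass
class Dataset:
    """Index-aligned records, responses, and (optionally) fingerprint matrix."""

    records: list[MoleculeRecord]
    endpoint: str
    y: np.ndarray
    X: np.ndarray | None = None
    scheme: str | None = None
    nbits: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def canonical_smiles(self) -> list[str]:
        return [r.smiles_canonical for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation partition specification (default 75/25)."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# potency scaling


def scale_ic50(ic50_nM: float) -> float:
    """Map an IC50 in nM onto the censored [0, 1] spIC50 scale.

    Values at or above 10,000 nM map to 0, values at or below 1.0 nM map
    to 1.0, and the interior follows (4 - log10 IC50) / 4.  The transform
    is monotone non-increasing in IC50.
    """
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    if ic50_nM >= IC50_UPPER_NM:
        return 0.0
    if ic50_nM <= IC50_LOWER_NM:
        return 1.0
    return (4.0 - math.log10(ic50_nM)) / 4.0


def sp_to_pic50(sp: float) -> float:
    """Convert scaled potency to -pIC50: -log10(1e-9 * 10^(4 - 4 sp)) = 5 + 4 sp."""
    if not 0.0 <= sp <= 1.0:
        raise ValueError(f"spIC50 must lie in [0, 1], got {sp}")
    return 5.0 + 4.0 * sp


def pic50_to_sp(pic50: float) -> float:
    """Algebraic inverse of :func:`sp_to_pic50`: sp = (pIC50 - 5) / 4."""
    if not 5.0 <= pic50 <= 9.0 + 1e-12:
        raise ValueError(f"-pIC50 must lie in [5, 9], got {pic50}")
    return (pic50 - 5.0) / 4.0


# ---------------------------------------------------------------------------
# structure handling


def canonicalize(smiles: str) -> str | None:
    """Largest-fragment canonical SMILES, or None if the input cannot be parsed.

    Fragment ties are broken by heavy-atom count, then molecular weight,
    then lexicographic canonical SMILES, so the outcome is deterministic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None

    def key(m: Chem.Mol) -> tuple:
        return (m.GetNumHeavyAtoms(), Descriptors.MolWt(m), Chem.MolToSmiles(m))

    best = max(frags, key=key)
    if best.GetNumHeavyAtoms() < 1:
        return None
    return Chem.MolToSmiles(best)


def _aggregate(values: Sequence[float], endpoint_kind: ActivityKind) -> float:
    """Merge duplicate measurements: geometric mean for IC50, arithmetic otherwise."""
    arr = np.asarray(values, dtype=float)
    if endpoint_kind == ActivityKind.ic50_nM:
        return float(np.exp(np.mean(np.log(arr))))
    return float(np.mean(arr))


def _endpoint_kind(units: str) -> ActivityKind:
    if units == "nM":
        return ActivityKind.ic50_nM
    if units == "logBB":
        return ActivityKind.logBB
    raise ValueError(f"unknown units {units!r}; expected 'nM' or 'logBB'")


def curate(
    raw_records: Iterable[tuple[str, str, str, float]],
    units: str = "nM",
) -> tuple[Dataset, dict]:
    """Curate raw (id, smiles, endpoint, value) rows into a Dataset.

    Rows with missing values are dropped, each structure is reduced to its
    largest fragment and canonicalized, unparsable SMILES are dropped with
    a warning, and records sharing a canonical SMILES are collapsed to a
    single record (geometric-mean IC50, arithmetic-mean logBB).  IC50
    responses are expressed on the spIC50 scale; logBB responses are kept
    as-is.

    Returns the curated dataset and a curation report of per-rule drop
    counts.  Raises :class:`CurationError` if everything is dropped or the
    rows mix endpoints.
    """
    kind = _endpoint_kind(units)
    report = {"input": 0, "missing_value": 0, "unparsable_smiles": 0,
              "duplicates_merged": 0, "kept": 0}

    endpoint: str | None = None
    by_canonical: dict[str, dict] = {}
    for rid, smiles, ep, value in raw_records:
        report["input"] += 1
        if endpoint is None:
            endpoint = ep
        elif ep != endpoint:
            raise CurationError(
                f"mixed endpoints in input: {endpoint!r} and {ep!r}")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            report["missing_value"] += 1
            continue
        canon = canonicalize(smiles)
        if canon is None:
            report["unparsable_smiles"] += 1
            logger.warning("dropping %s: unparsable SMILES %r", rid, smiles)
            continue
        entry = by_canonical.setdefault(
            canon, {"ids": [], "raw": smiles, "values": []})
        entry["ids"].append(str(rid))
        entry["values"].append(float(value))

    if report["input"] and not by_canonical:
        raise CurationError("all records were dropped during curation")

    records: list[MoleculeRecord] = []
    y: list[float] = []
    for canon, entry in by_canonical.items():
        if len(entry["values"]) > 1:
            report["duplicates_merged"] += len(entry["values"]) - 1
        merged = _aggregate(entry["values"], kind)
        act = ActivityValue(kind, merged)
        rec = MoleculeRecord(
            id=entry["ids"][0],
            smiles_raw=entry["raw"],
            smiles_canonical=canon,
            activities={endpoint or "": act},
        )
        records.append(rec)
        y.append(scale_ic50(merged) if kind == ActivityKind.ic50_nM else merged)

    report["kept"] = len(records)
    ds = Dataset(records=records, endpoint=endpoint or "", y=np.asarray(y, dtype=float))
    return ds, report


# ---------------------------------------------------------------------------
# fingerprints


def _generator(scheme: str, nbits: int):
    if scheme not in VALID_SCHEMES:
        raise ValueError(f"unknown fingerprint scheme {scheme!r}")
    if nbits not in VALID_NBITS:
        raise ValueError(f"nbits must be one of {VALID_NBITS}, got {nbits}")
    if scheme == "atompair":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=nbits)
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)


def fingerprint(smiles_or_record: str | MoleculeRecord,
                scheme: str = "atompair", nbits: int = 1024) -> Fingerprint:
    """Hashed binary fingerprint of a molecule.

    Deterministic and invariant to SMILES atom ordering (the structure is
    parsed, so any valid SMILES of the same molecule maps to identical bits).
    """
    smiles = (smiles_or_record.smiles_canonical
              if isinstance(smiles_or_record, MoleculeRecord)
              else smiles_or_record)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    gen = _generator(scheme, nbits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(scheme=scheme, nbits=nbits, bits=bits)


def featurize(ds: Dataset, scheme: str = "atompair", nbits: int = 1024) -> Dataset:
    """Return a copy of the dataset with the fingerprint matrix X attached."""
    gen = _generator(scheme, nbits)  # fail fast on bad config
    del gen
    X = np.vstack([
        fingerprint(r, scheme, nbits).bits for r in ds.records
    ]) if ds.records else np.zeros((0, nbits), dtype=np.uint8)
    return replace(ds, X=X, scheme=scheme, nbits=nbits)


# ---------------------------------------------------------------------------
# partitioning


def _subset(ds: Dataset, idx: np.ndarray) -> Dataset:
    return Dataset(
        records=[ds.records[i] for i in idx],
        endpoint=ds.endpoint,
        y=ds.y[idx],
        X=None if ds.X is None else ds.X[idx],
        scheme=ds.scheme,
        nbits=ds.nbits,
    )


def partition(ds: Dataset, spec: SplitSpec = SplitSpec()) -> tuple[Dataset, Dataset]:
    """Seeded random split into training and independent validation sets.

    The training set size is round(n * train_fraction); the two parts are
    disjoint and together cover the input.  Refuses to split fewer than
    4 records.
    """
    n = len(ds)
    if n < 4:
        raise ValueError(f"need at least 4 records to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(n * spec.train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    return _subset(ds, np.sort(perm[:n_train])), _subset(ds, np.sort(perm[n_train:]))


# ---------------------------------------------------------------------------
# I/O


def read_activity_csv(path) -> tuple[Dataset, dict]:
    """Read and curate a CSV with columns id, smiles, endpoint, value, units."""
    df = pd.read_csv(path)
    required = {"id", "smiles", "endpoint", "value", "units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
    units = df["units"].dropna().unique()
    if len(units) != 1:
        raise ValueError(f"expected a single units value, got {list(units)}")
    rows = [(r.id, r.smiles, r.endpoint, r.value) for r in df.itertuples()]
    return curate(rows, units=str(units[0]))


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi file (SMILES followed by an id per line) into (id, smiles) pairs."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol-{i}"
            out.append((mol_id, smiles))
    return out


def write_dataset_csv(ds: Dataset, path, units: str) -> None:
    """Write a curated dataset back to the id/smiles/endpoint/value/units CSV form."""
    value = ds.y
    if units == "nM":
        # invert the interior of the spIC50 scale; censored values sit at bounds
        value = np.power(10.0, 4.0 - 4.0 * ds.y)
    pd.DataFrame({
        "id": ds.ids,
        "smiles": ds.canonical_smiles,
        "endpoint": ds.endpoint,
        "value": value,
        "units": units,
    }).to_csv(path, index=False)
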