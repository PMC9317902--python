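"""Synthetic molecule libraries with a planted structure-activity relationship.

Desk-scale stand-in for the curated activity datasets the pipeline is
meant to consume (ChEMBL-style IC50 tables, a logBB permeation set, and
screening libraries).  Molecules are assembled by seeded random
single-bond combination of drug-like fragments; activity is planted
directly on fingerprint bits, latent = b0 + sum_j b_j * bit_j + noise, so
the structure-activity truth is exact by construction:

* ``logBB`` responses are the latent values themselves (defaults put
  them mostly within [-2, 1.5]);
* ``ic50_nM`` responses round-trip through the censored potency scale:
  the latent value is clamped to [0, 1], mapped to -pIC50 = 5 + 4*latent
  and then to IC50 = 10^(9 - pIC50) nM, so both censoring branches
  (1 nM and 10,000 nM) occur in realistic proportions.

Everything is deterministic per seed, down to the serialized files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import (ActivityKind, ActivityValue, Dataset, SplitSpec, curate,
                   featurize, partition, scale_ic50)

__all__ = ["SyntheticConfig", "PlantedTruth", "SyntheticBenchmark",
           "FRAGMENT_POOL", "generate_library", "plant_activity",
           "make_benchmark"]

# ~30 drug-like building blocks, including the quinazoline / morpholine /
# aniline motifs typical of kinase-inhibitor chemotypes
FRAGMENT_POOL: tuple[str, ...] = (
    "c1ccccc1",            # benzene
    "Nc1ccccc1",           # aniline
    "Oc1ccccc1",           # phenol
    "Cc1ccccc1",           # toluene
    "COc1ccccc1",          # anisole
    "Fc1ccccc1",           # fluorobenzene
    "Clc1ccccc1",          # chlorobenzene
    "Brc1ccccc1",          # bromobenzene
    "N#Cc1ccccc1",         # benzonitrile
    "NC(=O)c1ccccc1",      # benzamide
    "NS(=O)(=O)c1ccccc1",  # benzenesulfonamide
    "OC(=O)c1ccccc1",      # benzoic acid
    "c1ccncc1",            # pyridine
    "c1cnc2ccccc2n1",      # quinoxaline
    "Nc1ncnc2ccccc12",     # 4-aminoquinazoline
    "c1ccc2ccccc2c1",      # naphthalene
    "c1cc[nH]c1",          # pyrrole
    "c1cn[nH]c1",          # pyrazole
    "c1c[nH]cn1",          # imidazole
    "c1ccoc1",             # furan
    "c1ccsc1",             # thiophene
    "C1CCNCC1",            # piperidine
    "C1CNCCN1",            # piperazine
    "C1COCCN1",            # morpholine
    "C1CCOC1",             # tetrahydrofuran
    "C1CCCCC1",            # cyclohexane
    "C=CC(N)=O",           # acrylamide
    "CCO",                 # ethanol
    "CCN",                 # ethylamine
    "CC(C)C",              # isobutane
)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard benchmark conditions."""

    n_molecules: int = 300
    seed: int = 0
    endpoint_kind: str = "ic50_nM"          # or "logBB"
    endpoint: str = "target"
    n_informative_bits: int = 5
    effect_sizes: float | list[float] = 0.3
    intercept: float | None = None          # None -> endpoint-specific default
    noise_sd: float = 0.05
    scheme: str = "atompair"
    nbits: int = 256
    fragment_pool: tuple[str, ...] = FRAGMENT_POOL
    min_fragments: int = 2
    max_fragments: int = 4

    def resolved_intercept(self) -> float:
        if self.intercept is not None:
            return self.intercept
        # ic50: latent spread roughly [-0.2, 1.3] so both censoring branches occur;
        # logBB: responses land mostly within [-2, 1.5]
        return -0.2 if self.endpoint_kind == "ic50_nM" else -0.5

    def resolved_effects(self) -> np.ndarray:
        if np.isscalar(self.effect_sizes):
            default = 0.3 if self.endpoint_kind == "ic50_nM" else 0.4
            size = float(self.effect_sizes) if self.effect_sizes else default
            return np.full(self.n_informative_bits, size)
        arr = np.asarray(self.effect_sizes, dtype=float)
        if arr.size != self.n_informative_bits:
            raise ValueError("effect_sizes length must equal n_informative_bits")
        return arr


@dataclass
class PlantedTruth:
    """Exact bit-level structure-activity ground truth of a benchmark."""

    informative_bits: np.ndarray
    coefficients: np.ndarray
    intercept: float
    latent: np.ndarray       # noiseless latent, b0 + X[:, bits] @ beta

    def to_dict(self) -> dict:
        return {
            "informative_bits": [int(b) for b in self.informative_bits],
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "latent": [float(v) for v in self.latent],
        }


@dataclass
class SyntheticBenchmark:
    """A generated library with planted truth and a 75/25 split."""

    library: Dataset
    truth: PlantedTruth
    train: Dataset
    ivs: Dataset
    config: SyntheticConfig = field(default_factory=SyntheticConfig)


# ---------------------------------------------------------------------------
# library generation


def _attach(mol_a: Chem.Mol, mol_b: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join two fragments by a single bond between atoms with a free hydrogen."""
    cand_a = [a.GetIdx() for a in mol_a.GetAtoms() if a.GetTotalNumHs() > 0]
    cand_b = [a.GetIdx() for a in mol_b.GetAtoms() if a.GetTotalNumHs() > 0]
    if not cand_a or not cand_b:
        return None
    combo = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    ia = int(rng.choice(cand_a))
    ib = int(rng.choice(cand_b)) + mol_a.GetNumAtoms()
    combo.AddBond(ia, ib, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def generate_library(cfg: SyntheticConfig) -> list[tuple[str, str]]:
    """Assemble ``n_molecules`` unique molecules as (id, SMILES) pairs.

    Each molecule combines 2-4 random fragments via single-bond
    attachment; infeasible attachments are resampled within a bounded
    retry budget, and the output is deduplicated on canonical SMILES.
    """
    if not cfg.fragment_pool:
        raise ValueError("fragment pool is empty")
    pool = [Chem.MolFromSmiles(s) for s in cfg.fragment_pool]
    if any(m is None for m in pool):
        bad = [s for s, m in zip(cfg.fragment_pool, pool) if m is None]
        raise ValueError(f"invalid fragment SMILES: {bad}")
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    attempts = 0
    max_attempts = max(200, 60 * cfg.n_molecules)
    while len(out) < cfg.n_molecules and attempts < max_attempts:
        attempts += 1
        n_frag = int(rng.integers(cfg.min_fragments, cfg.max_fragments + 1))
        mol = pool[int(rng.integers(len(pool)))]
        ok = True
        for _ in range(n_frag - 1):
            nxt = pool[int(rng.integers(len(pool)))]
            mol = _attach(mol, nxt, rng)
            if mol is None:
                ok = False
                break
        if not ok:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append((f"syn-{len(out) + 1:04d}", smiles))
    return out


# ---------------------------------------------------------------------------
# planted activity


def plant_activity(library: list[tuple[str, str]],
                   cfg: SyntheticConfig) -> tuple[Dataset, PlantedTruth]:
    """Plant a linear bit-level activity signal on a generated library.

    Informative bits are drawn among bits with prevalence in [0.1, 0.9]
    across the library so the signal is learnable.  Returns the curated,
    featurized dataset (response on the spIC50 scale for ic50 endpoints,
    raw latent scale for logBB) and the exact planted truth.
    """
    if not library:
        raise ValueError("library is empty")
    units = "nM" if cfg.endpoint_kind == "ic50_nM" else "logBB"
    # placeholder activities; real responses are planted below
    ds, _ = curate([(i, s, cfg.endpoint, 1.0) for i, s in library], units=units)
    ds = featurize(ds, cfg.scheme, cfg.nbits)
    X = np.asarray(ds.X, dtype=float)

    prevalence = X.mean(axis=0)
    eligible = np.flatnonzero((prevalence >= 0.1) & (prevalence <= 0.9))
    if eligible.size < cfg.n_informative_bits:
        raise ValueError(
            f"only {eligible.size} bits have prevalence in [0.1, 0.9]; "
            "generate a larger or more diverse library")
    rng = np.random.default_rng(cfg.seed + 1)
    bits = np.sort(rng.choice(eligible, size=cfg.n_informative_bits, replace=False))
    beta = cfg.resolved_effects()
    b0 = cfg.resolved_intercept()
    latent = b0 + X[:, bits] @ beta
    noisy = latent + rng.normal(0.0, cfg.noise_sd, size=len(ds))

    if cfg.endpoint_kind == "ic50_nM":
        pic50 = 5.0 + 4.0 * np.clip(noisy, 0.0, 1.0)
        ic50 = np.power(10.0, 9.0 - pic50)
        y = np.array([scale_ic50(v) for v in ic50])
        for rec, v in zip(ds.records, ic50):
            rec.activities[cfg.endpoint] = ActivityValue(ActivityKind.ic50_nM, float(v))
    else:
        y = noisy
        for rec, v in zip(ds.records, y):
            rec.activities[cfg.endpoint] = ActivityValue(ActivityKind.logBB, float(v))
    ds.y = y
    truth = PlantedTruth(informative_bits=bits, coefficients=beta,
                         intercept=b0, latent=latent)
    return ds, truth


# ---------------------------------------------------------------------------
# full benchmark


def make_benchmark(cfg: SyntheticConfig,
                   outdir: str | Path | None = None) -> SyntheticBenchmark:
    """Generate library + planted activity + 75/25 split, optionally on disk.

    When ``outdir`` is given, writes ``library.smi``, ``activities.csv``,
    ``truth.json`` and ``split.json`` in the same formats the real
    pipeline consumes; all artifacts are byte-identical across runs with
    the same config.
    """
    library = generate_library(cfg)
    ds, truth = plant_activity(library, cfg)
    train, ivs = partition(ds, SplitSpec(train_fraction=0.75, seed=cfg.seed))
    bench = SyntheticBenchmark(library=ds, truth=truth, train=train,
                               ivs=ivs, config=cfg)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "library.smi", "w") as fh:
            for rec in ds.records:
                fh.write(f"{rec.smiles_canonical}\t{rec.id}\n")
        units = "nM" if cfg.endpoint_kind == "ic50_nM" else "logBB"
        if cfg.endpoint_kind == "ic50_nM":
            values = [rec.activities[cfg.endpoint].value for rec in ds.records]
        else:
            values = list(ds.y)
        pd.DataFrame({
            "id": ds.ids, "smiles": ds.canonical_smiles,
            "endpoint": cfg.endpoint, "value": values, "units": units,
        }).to_csv(outdir / "activities.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        (outdir / "split.json").write_text(json.dumps({
            "seed": cfg.seed, "train_fraction": 0.75,
            "train": train.ids, "ivs": ivs.ids,
        }, indent=1))
    return bench
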