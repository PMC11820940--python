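"""Synthetic marker and phenotype generation.

Markers are drawn at Hardy-Weinberg proportions (dosage ~ Binomial(2, p)
with allele frequency p uniform over a MAF range).  Phenotypes follow the
additive polygenic model y = mu + W beta + e: standard-normal effects on a
random QTL subset, centered dosages W, and residuals scaled so the realized
in-sample variance ratio var(W beta) / (var(W beta) + var(e)) equals the
target heritability exactly — giving recovery tests a sharp truth value.
Traits and environments get independent effect draws (no genotype x
environment interaction, matching per-environment model fitting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MarkerMatrix, PhenotypeTable, write_markers, write_phenotypes

__all__ = ["SimulationConfig", "simulate_markers", "simulate_phenotypes",
           "make_fixture_bundle", "PRESETS"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the replicate design used throughout the test suite:
    300 lines x 500 SNPs, 50 QTL, heritability 0.5.
    """

    n_lines: int = 300
    n_markers: int = 500
    n_qtl: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.5
    mu: float = 10.0
    n_traits: int = 1
    n_environments: int = 1
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimulationConfig.seed is mandatory")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.n_qtl == 0 and self.h2 > 0:
            raise ValueError("n_qtl = 0 is inconsistent with h2 > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")


def simulate_markers(cfg: SimulationConfig) -> MarkerMatrix:
    """Hardy-Weinberg dosages, one allele frequency per marker."""
    rng = np.random.default_rng(cfg.seed)
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    dosages = rng.binomial(2, freqs, size=(cfg.n_lines, cfg.n_markers)).astype(float)
    line_ids = [f"L{i + 1:04d}" for i in range(cfg.n_lines)]
    marker_ids = [f"M{j + 1:05d}" for j in range(cfg.n_markers)]
    return MarkerMatrix(line_ids, marker_ids, dosages)


def simulate_phenotypes(m: MarkerMatrix, cfg: SimulationConfig) -> tuple[PhenotypeTable, dict]:
    """Additive phenotypes with exactly realized heritability.

    Returns the phenotype table and a truth record (QTL indices, effects,
    genetic values and realized h2 per trait x environment).
    """
    rng = np.random.default_rng(cfg.seed + 1 if cfg.seed < 2**31 - 2 else cfg.seed - 1)
    W = m.dosages - m.dosages.mean(axis=0)
    records, truth = [], {"seed": cfg.seed, "h2": cfg.h2, "combos": {}}
    for t in range(cfg.n_traits):
        for e in range(cfg.n_environments):
            trait, env = f"trait{t + 1}", f"env{e + 1}"
            qtl = np.sort(rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False))
            beta = rng.standard_normal(cfg.n_qtl)
            gv = W[:, qtl] @ beta
            var_g = float(np.var(gv))
            if var_g <= 0:
                raise ValueError("degenerate genetic values (all QTL monomorphic?)")
            e_raw = rng.standard_normal(cfg.n_lines)
            e_raw = e_raw - e_raw.mean()
            target_sd = np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2)
            resid = e_raw / np.std(e_raw) * target_sd
            y = cfg.mu + gv + resid
            realized = var_g / (var_g + float(np.var(resid)))
            truth["combos"][f"{env}:{trait}"] = {
                "qtl": qtl.tolist(),
                "effects": beta.tolist(),
                "genetic_values": gv.tolist(),
                "realized_h2": realized,
            }
            for lid, val in zip(m.line_ids, y):
                records.append({"line_id": lid, "environment": env,
                                "trait": trait, "value": val})
    table = PhenotypeTable(pd.DataFrame(records))
    return table, truth


PRESETS: dict[str, SimulationConfig] = {
    # quick end-to-end runs
    "tiny": SimulationConfig(n_lines=60, n_markers=200, n_qtl=30, h2=0.5,
                             n_traits=1, n_environments=1, seed=0),
    # mirrors the maize benchmark shape: 1000 lines x 4085 markers, 11 envs, 4 traits
    "maize_shape": SimulationConfig(n_lines=1000, n_markers=4085, n_qtl=200, h2=0.5,
                                    n_traits=4, n_environments=11, seed=0),
}


def make_fixture_bundle(preset: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a ready-made dataset (markers CSV, phenotypes CSV, truth JSON)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    base = PRESETS[preset]
    cfg = SimulationConfig(**{**asdict(base), "seed": seed,
                              "maf_range": tuple(base.maf_range)})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    markers = simulate_markers(cfg)
    phenotypes, truth = simulate_phenotypes(markers, cfg)
    paths = {
        "markers": write_markers(markers, outdir / f"{preset}_markers.csv"),
        "phenotypes": write_phenotypes(phenotypes, outdir / f"{preset}_phenotypes.csv"),
        "truth": outdir / f"{preset}_truth.json",
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
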