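"""Synthetic mapping populations and the replicated bias/equivalence studies.

Two study designs:

F2 single-marker
    Genotypes segregate 1:2:1 ({+1, 0, -1} with probabilities .25/.5/.25),
    the code is standardized per replicate, and y = mu + z alpha + eps with
    eps ~ N(0, sigma^2).  Defaults mu = 10, sigma^2 = 20.  This is the
    interval-mapping setting with no polygenic background.

Full-sib polygenic
    n_families families of m_sibs full siblings; the numerator matrix has
    compound-symmetry blocks (0.5 off-diagonal).  The polygenic value is a
    family effect plus an individual deviation, each with variance
    sigma_xi^2 / 2, so within-family covariance is sigma_xi^2 / 2.  Defaults
    mu = 0, sigma_xi^2 = sigma^2 = 10.

In both designs the true squared QTL effect for a target heritability h2 is
alpha^2 = h2 / (1 - h2) * (sigma_xi^2 + sigma^2).

The experiment drivers replicate these designs, fit the naive squared,
moment (with and without truncation) and REML random-model estimators per
replicate, and aggregate following the convention of computing the mean
variance estimate first and the heritability from that mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genodata import GenotypeVector, KinshipMatrix, fullsib_numerator_matrix, standardize_genotypes
from .lmm import FixedQTLModel, RandomQTLModel

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationDesign",
    "ExperimentResult",
    "effect_from_heritability",
    "full_heritability_grid",
    "simulate_f2_single_marker",
    "simulate_fullsib_polygenic",
    "run_bias_experiment",
    "run_equivalence_experiment",
]

_GENO_CODES = np.array([1.0, 0.0, -1.0])
_GENO_PROBS = np.array([0.25, 0.5, 0.25])
_MAX_REDRAWS = 100


class Effect(NamedTuple):
    alpha: float
    alpha2: float


def effect_from_heritability(h2: float, sigma_xi2: float, sigma2: float) -> Effect:
    """QTL effect implied by a target heritability.

    alpha^2 = h2/(1-h2) * (sigma_xi2 + sigma2); the positive root is
    returned alongside the square.  Use sigma_xi2 = 0 for designs without a
    polygenic component.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"heritability must be in [0, 1), got {h2}")
    a2 = h2 / (1.0 - h2) * (sigma_xi2 + sigma2)
    return Effect(float(np.sqrt(a2)), float(a2))


def full_heritability_grid() -> np.ndarray:
    """The fine heritability grid 0 to 0.2 in steps of 0.001 (201 points)."""
    return np.round(np.arange(0, 201) * 0.001, 3)


def _draw_genotypes(n: int, rng: np.random.Generator) -> np.ndarray:
    for attempt in range(_MAX_REDRAWS):
        g = rng.choice(_GENO_CODES, size=n, p=_GENO_PROBS)
        if np.unique(g).size >= 2:
            if attempt:
                logger.info("redrew a monomorphic marker (%d attempt(s))", attempt)
            return g
    raise RuntimeError(f"drew a monomorphic marker {_MAX_REDRAWS} times in a row (n={n})")


def simulate_f2_single_marker(
    n: int,
    h2: float,
    mu: float = 10.0,
    sigma2: float = 20.0,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GenotypeVector]:
    """One F2 single-marker replicate: returns (trait, genotype)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    g = _draw_genotypes(n, rng)
    z = standardize_genotypes(g)
    alpha = effect_from_heritability(h2, 0.0, sigma2).alpha
    y = mu + z * alpha + rng.normal(0.0, np.sqrt(sigma2), size=n)
    return y, GenotypeVector(raw_codes=g, standardized=z)


def simulate_fullsib_polygenic(
    n_families: int,
    m_sibs: int,
    h2: float,
    sigma_xi2: float = 10.0,
    sigma2: float = 10.0,
    mu: float = 0.0,
    seed=None,
    rng: np.random.Generator | None = None,
    kinship: KinshipMatrix | None = None,
) -> tuple[np.ndarray, GenotypeVector, KinshipMatrix]:
    """One full-sib polygenic replicate: returns (trait, genotype, kinship).

    The polygenic vector is family effect + within-family deviation, each
    with variance sigma_xi^2 / 2, matching the compound-symmetry numerator
    matrix with coefficient 1/2.
    """
    n = n_families * m_sibs
    if n < 3:
        raise ValueError("need n_families * m_sibs >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    if kinship is None:
        kinship = fullsib_numerator_matrix(n_families, m_sibs)
    g = _draw_genotypes(n, rng)
    z = standardize_genotypes(g)
    alpha = effect_from_heritability(h2, sigma_xi2, sigma2).alpha
    fam = rng.normal(0.0, np.sqrt(sigma_xi2 / 2.0), size=n_families)
    xi = np.repeat(fam, m_sibs) + rng.normal(0.0, np.sqrt(sigma_xi2 / 2.0), size=n)
    y = mu + z * alpha + xi + rng.normal(0.0, np.sqrt(sigma2), size=n)
    return y, GenotypeVector(raw_codes=g, standardized=z), kinship


@dataclass
class SimulationDesign:
    """Study conditions for a replicated simulation experiment.

    ``mu``/``sigma2``/``sigma_xi2`` default to the design's standard values
    when left as None: (10, 20, 0) for the F2 single-marker design and
    (0, 10, 10) for the full-sib polygenic design.
    """

    population: str = "f2_single_marker"  # or "fullsib_polygenic"
    n: int = 100
    n_families: int = 10
    m_sibs: int = 5
    h2_grid: tuple = (0.05, 0.10, 0.15, 0.20)
    mu: float | None = None
    sigma_xi2: float | None = None
    sigma2: float | None = None
    n_replicates: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.population not in ("f2_single_marker", "fullsib_polygenic"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.population == "f2_single_marker":
            self.mu = 10.0 if self.mu is None else self.mu
            self.sigma2 = 20.0 if self.sigma2 is None else self.sigma2
            self.sigma_xi2 = 0.0 if self.sigma_xi2 is None else self.sigma_xi2
            if self.n < 3:
                raise ValueError("need n >= 3")
        else:
            self.mu = 0.0 if self.mu is None else self.mu
            self.sigma2 = 10.0 if self.sigma2 is None else self.sigma2
            self.sigma_xi2 = 10.0 if self.sigma_xi2 is None else self.sigma_xi2
            if self.n_families * self.m_sibs < 3:
                raise ValueError("need n_families * m_sibs >= 3")
        for h in self.h2_grid:
            if not 0.0 <= h < 1.0:
                raise ValueError(f"heritability {h} outside [0, 1)")
        if self.sigma2 < 0 or self.sigma_xi2 < 0:
            raise ValueError("variances must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def sample_size(self) -> int:
        return self.n if self.population == "f2_single_marker" else self.n_families * self.m_sibs

    def rng(self, grid_index: int, replicate: int) -> np.random.Generator:
        """One deterministic substream per (grid point, replicate)."""
        return np.random.default_rng([int(self.seed), int(grid_index), int(replicate)])

    def to_config(self) -> str:
        keys = (
            "population n n_families m_sibs mu sigma_xi2 sigma2 n_replicates seed".split()
        )
        lines = [f"{k} = {getattr(self, k)}" for k in keys]
        lines.append("h2_grid = " + ",".join(str(h) for h in self.h2_grid))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SimulationDesign":
        kw = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "population":
                kw[key] = val
            elif key == "h2_grid":
                kw[key] = tuple(float(v) for v in val.split(","))
            elif key in ("n", "n_families", "m_sibs", "n_replicates", "seed"):
                kw[key] = int(val)
            elif key in ("mu", "sigma_xi2", "sigma2"):
                kw[key] = float(val)
            else:
                raise ValueError(f"unknown design key {key!r}")
        return cls(**kw)


@dataclass
class ExperimentResult:
    """Per-replicate estimates and per-grid-point aggregates."""

    design: SimulationDesign
    replicates: pd.DataFrame
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.summary is None:
            self.summary = self._aggregate()

    def _aggregate(self) -> pd.DataFrame:
        df = self.replicates
        ok = df[df["converged"]]
        rows = []
        xi = 0.0 if self.design.population == "f2_single_marker" else self.design.sigma_xi2
        for h2, grp in ok.groupby("h2_true", sort=True):
            rec = {
                "h2_true": h2,
                "sigma_alpha2_true": grp["sigma_alpha2_true"].iloc[0],
                "n_used": len(grp),
                "n_failed": int((df["h2_true"] == h2).sum() - len(grp)),
                "mean_s2_alpha": grp["s_alpha2"].mean(),
            }
            for m in ("naive", "moment", "moment_truncated", "reml"):
                if m in grp:
                    vbar = grp[m].mean()
                    rec[f"mean_{m}"] = vbar
                    # heritability from the averaged variance estimate
                    rec[f"h2_{m}"] = max(vbar, 0.0) / (max(vbar, 0.0) + xi + self.design.sigma2)
            rows.append(rec)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.replicates.to_csv(path, sep="\t", index=False)


def _simulate_once(design: SimulationDesign, h2: float, rng, kinship):
    if design.population == "f2_single_marker":
        y, geno = simulate_f2_single_marker(
            design.n, h2, mu=design.mu, sigma2=design.sigma2, rng=rng
        )
        return y, geno, None
    y, geno, _ = simulate_fullsib_polygenic(
        design.n_families,
        design.m_sibs,
        h2,
        sigma_xi2=design.sigma_xi2,
        sigma2=design.sigma2,
        mu=design.mu,
        rng=rng,
        kinship=kinship,
    )
    return y, geno, kinship


def run_bias_experiment(
    design: SimulationDesign,
    methods: tuple[str, ...] = ("naive", "moment", "reml"),
) -> ExperimentResult:
    """Replicated comparison of the naive, moment and REML estimators.

    For each grid point and replicate the fixed model supplies the naive
    squared estimate, the untruncated and truncated moment estimates and the
    squared standard error; the random model supplies the REML estimate.
    Non-convergent replicates are flagged and excluded from the aggregates.
    """
    kin = (
        fullsib_numerator_matrix(design.n_families, design.m_sibs)
        if design.population == "fullsib_polygenic"
        else None
    )
    rows = []
    for gi, h2 in enumerate(design.h2_grid):
        a2_true = effect_from_heritability(h2, design.sigma_xi2, design.sigma2).alpha2
        for rep in range(design.n_replicates):
            rng = design.rng(gi, rep)
            y, geno, _ = _simulate_once(design, h2, rng, kin)
            rec = {
                "h2_true": h2,
                "sigma_alpha2_true": a2_true,
                "replicate": rep,
                "converged": True,
            }
            try:
                fixed = FixedQTLModel(kinship=kin).fit(geno.standardized, y)
                rec["s_alpha2"] = fixed.s_alpha_ ** 2
                if "naive" in methods:
                    rec["naive"] = fixed.alpha_ ** 2
                if "moment" in methods:
                    rec["moment"] = fixed.qtl_variance_raw_
                    rec["moment_truncated"] = fixed.qtl_variance_
                if "reml" in methods:
                    random_fit = RandomQTLModel(kinship=kin).fit(geno.standardized, y)
                    rec["reml"] = random_fit.sigma_alpha2_
                    rec["reml_boundary"] = random_fit.boundary_
            except (ValueError, RuntimeError) as exc:
                logger.warning("replicate (%s, %d) failed: %s", h2, rep, exc)
                rec["converged"] = False
            rows.append(rec)
    return ExperimentResult(design=design, replicates=pd.DataFrame(rows))


def run_equivalence_experiment(design: SimulationDesign, atol: float = 1e-4) -> ExperimentResult:
    """Pair the truncated moment estimate with the REML estimate per replicate.

    The summary carries the fraction of pairs agreeing within ``atol``;
    disagreements are expected only for occasional local-convergence or
    boundary cases of the three-component REML fit.
    """
    if design.population != "fullsib_polygenic":
        raise ValueError("the equivalence experiment uses the full-sib polygenic design")
    kin = fullsib_numerator_matrix(design.n_families, design.m_sibs)
    rows = []
    for gi, h2 in enumerate(design.h2_grid):
        a2_true = effect_from_heritability(h2, design.sigma_xi2, design.sigma2).alpha2
        for rep in range(design.n_replicates):
            rng = design.rng(gi, rep)
            y, geno, _ = _simulate_once(design, h2, rng, kin)
            rec = {
                "h2_true": h2,
                "sigma_alpha2_true": a2_true,
                "replicate": rep,
                "converged": True,
            }
            try:
                fixed = FixedQTLModel(kinship=kin).fit(geno.standardized, y)
                random_fit = RandomQTLModel(kinship=kin).fit(geno.standardized, y)
                rec["moment_truncated"] = fixed.qtl_variance_
                rec["reml"] = random_fit.sigma_alpha2_
                rec["reml_boundary"] = random_fit.boundary_
                rec["agree"] = abs(fixed.qtl_variance_ - random_fit.sigma_alpha2_) <= atol
            except (ValueError, RuntimeError) as exc:
                logger.warning("replicate (%s, %d) failed: %s", h2, rep, exc)
                rec["converged"] = False
            rows.append(rec)
    reps = pd.DataFrame(rows)
    ok = reps[reps["converged"]]
    summary = (
        ok.groupby("h2_true")
        .agg(agreement_fraction=("agree", "mean"), n_used=("agree", "size"))
        .reset_index()
    )
    result = ExperimentResult(design=design, replicates=reps, summary=summary)
    return result
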