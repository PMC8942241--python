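"""Genome-scan driver: per-marker QTL tests and variance/heritability profiles.

Two mapping strategies:

interval
    single-locus fits without a polygenic term (the fixed model is ordinary
    least squares);

polygenic
    the marker-inferred kinship enters every fit as the covariance of a
    polygenic random effect, shrinking background signal.

Under either strategy the locus may be treated as fixed (moment variance,
Wald test) or random (REML variance component; the Wald test is still taken
from the companion fixed fit).  Pseudo markers are inserted on a cM grid as
Haley-Knott style conditional expectations of the F2 genotype code given the
flanking markers under a Haldane map.  The Bonferroni threshold counts real
markers only; pseudo markers are tested but not counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lmm import FixedQTLModel, RandomQTLModel, bonferroni_wald_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "genome_scan",
    "impute_pseudo_markers",
    "summarize_scan",
    "haldane_recombination",
    "expected_f2_code",
]

_SCAN_COLUMNS = [
    "marker",
    "chromosome",
    "position",
    "is_pseudo",
    "alpha_hat",
    "s_alpha",
    "wald",
    "p_value",
    "sigma_qtl2",
    "sigma_alpha2",
    "h2_corrected",
    "h2_naive",
    "converged",
]


def haldane_recombination(distance_cm: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM."""
    if distance_cm < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * distance_cm / 100.0))


def _f2_transition(r: float) -> np.ndarray:
    """Genotype transition probabilities between two F2 loci at recombination r.

    Rows and columns are ordered (+1, 0, -1); rows condition on the left
    locus.  Each of the two parental gametes recombines independently.
    """
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2.0 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2.0 * r * s, s * s],
        ]
    )


_CODE_INDEX = {1: 0, 0: 1, -1: 2}
_CODES = np.array([1.0, 0.0, -1.0])


def expected_f2_code(left_code, right_code, r_left: float, r_right: float) -> float:
    """Conditional expectation of the F2 code at a position between two markers.

    ``r_left``/``r_right`` are the recombination fractions from the flanking
    markers to the position.  P(g | gL, gR) is proportional to
    T(r_left)[gL, g] * T(r_right)[g, gR].
    """
    TL = _f2_transition(r_left)
    TR = _f2_transition(r_right)
    il = _CODE_INDEX[int(left_code)]
    ir = _CODE_INDEX[int(right_code)]
    w = TL[il, :] * TR[:, ir]
    return float(_CODES @ w / w.sum())


def impute_pseudo_markers(
    markers: pd.DataFrame, map_table: pd.DataFrame, step_cm: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Insert expected-code pseudo markers every ``step_cm`` along each chromosome.

    Positions are placed on a per-interval grid (left + k*step, strictly
    inside the interval).  Real markers pass through unchanged.  Returns the
    augmented genotype table and a map table with an ``is_pseudo`` column,
    both ordered by chromosome and position.

    Raw F2 codes {+1, 0, -1} are required at the real markers.
    """
    if step_cm <= 0:
        raise ValueError("step must be positive")
    markers = markers.copy()
    markers.columns = [str(c) for c in markers.columns]
    out_geno = {}
    rows = []
    for chrom, grp in map_table.groupby("chromosome", sort=False):
        grp = grp.sort_values("position")
        names = list(grp["marker"])
        pos = grp["position"].to_numpy(dtype=float)
        if len(names) < 2:
            logger.warning("chromosome %s has a single marker; no pseudo markers inserted", chrom)
        for name, p in zip(names, pos):
            out_geno[name] = markers[name].to_numpy(dtype=float)
            rows.append({"marker": name, "chromosome": chrom, "position": p, "is_pseudo": False})
        for i in range(len(names) - 1):
            left, right = names[i], names[i + 1]
            p0, p1 = pos[i], pos[i + 1]
            gl = markers[left].to_numpy(dtype=float)
            gr = markers[right].to_numpy(dtype=float)
            k = 1
            while p0 + k * step_cm < p1 - 1e-9:
                p = p0 + k * step_cm
                r1 = haldane_recombination(p - p0)
                r2 = haldane_recombination(p1 - p)
                # 3x3 lookup of expected codes for the 9 flanking combinations
                table = {
                    (a, b): expected_f2_code(a, b, r1, r2) for a in (1, 0, -1) for b in (1, 0, -1)
                }
                code = np.array([table[(int(a), int(b))] for a, b in zip(gl, gr)])
                name = f"{left}~{p:g}cM"
                out_geno[name] = code
                rows.append(
                    {"marker": name, "chromosome": chrom, "position": p, "is_pseudo": True}
                )
                k += 1
    aug_map = (
        pd.DataFrame(rows)
        .sort_values(["chromosome", "position"], kind="stable")
        .reset_index(drop=True)
    )
    aug_geno = pd.DataFrame(out_geno)[list(aug_map["marker"])]
    return aug_geno, aug_map


def genome_scan(
    markers: pd.DataFrame,
    y,
    covariates=None,
    kinship=None,
    model: str = "fixed",
    method: str = "interval",
    map_table: pd.DataFrame | None = None,
    pseudo_step: float | None = None,
    verbosity: int = 0,
) -> pd.DataFrame:
    """Scan every marker position; one row per position.

    The fixed model supplies the effect, Wald test and truncated moment
    variance at each position; with ``model='random'`` a REML variance
    component is estimated as well.  Per-marker failures are logged and
    flagged, and the scan continues.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    if method not in ("interval", "polygenic"):
        raise ValueError(f"method must be 'interval' or 'polygenic', got {method!r}")
    if method == "polygenic" and kinship is None:
        raise ValueError("polygenic mapping requires a kinship matrix")
    kin = kinship if method == "polygenic" else None
    y = np.asarray(y, dtype=float).ravel()

    if map_table is not None and pseudo_step is not None:
        markers, map_table = impute_pseudo_markers(markers, map_table, pseudo_step)
    markers = markers.copy()
    markers.columns = [str(c) for c in markers.columns]
    if map_table is not None:
        order = list(map_table["marker"])
        meta = map_table.set_index("marker")
    else:
        order = list(markers.columns)
        meta = None

    rows = []
    for i, name in enumerate(order):
        rec = {"marker": name, "chromosome": None, "position": np.nan, "is_pseudo": False}
        if meta is not None:
            rec["chromosome"] = meta.loc[name, "chromosome"]
            rec["position"] = float(meta.loc[name, "position"])
            rec["is_pseudo"] = bool(meta.loc[name].get("is_pseudo", False))
        try:
            fixed = FixedQTLModel(kinship=kin, marker_name=name).fit(
                markers[name].to_numpy(), y, covariates=covariates
            )
            rec.update(
                alpha_hat=fixed.alpha_,
                s_alpha=fixed.s_alpha_,
                wald=fixed.wald_,
                p_value=fixed.p_value_,
                sigma_qtl2=fixed.qtl_variance_,
                sigma_alpha2=np.nan,
                h2_corrected=fixed.h2_,
                h2_naive=fixed.h2_naive_,
                converged=bool(fixed.converged_),
            )
            if model == "random":
                rnd = RandomQTLModel(kinship=kin, marker_name=name).fit(
                    markers[name].to_numpy(), y, covariates=covariates
                )
                rec["sigma_alpha2"] = rnd.sigma_alpha2_
                rec["h2_corrected"] = rnd.h2_
                rec["converged"] = rec["converged"] and bool(rnd.converged_)
        except (ValueError, RuntimeError) as exc:
            logger.warning("marker %s failed: %s", name, exc)
            rec.update(
                alpha_hat=np.nan, s_alpha=np.nan, wald=np.nan, p_value=np.nan,
                sigma_qtl2=np.nan, sigma_alpha2=np.nan, h2_corrected=np.nan,
                h2_naive=np.nan, converged=False,
            )
        if verbosity >= 1:
            logger.info("scanned %s (%d/%d)", name, i + 1, len(order))
        rows.append(rec)
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


def summarize_scan(rows: pd.DataFrame, n_real_markers: int, alpha: float = 0.05) -> dict:
    """Significance calls and naive-vs-corrected bias for a scan table.

    The Bonferroni Wald threshold uses the number of real markers only.  The
    per-row relative bias is (h2_naive - h2_corrected) / h2_corrected, NaN
    where the corrected heritability is zero.
    """
    if len(rows) == 0:
        raise ValueError("empty scan table")
    threshold = bonferroni_wald_threshold(n_real_markers, alpha)
    out = rows.copy()
    out["significant"] = out["wald"] >= threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        out["relative_bias"] = np.where(
            out["h2_corrected"] > 0,
            (out["h2_naive"] - out["h2_corrected"]) / out["h2_corrected"],
            np.nan,
        )
    return {
        "threshold": threshold,
        "n_real_markers": int(n_real_markers),
        "alpha": alpha,
        "rows": out,
        "significant": out[out["significant"].fillna(False)],
        "n_significant": int(out["significant"].fillna(False).sum()),
    }
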