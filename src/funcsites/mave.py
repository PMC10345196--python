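"""Derive 4-class training labels from paired MAVE score distributions.

Multiplexed assays of variant effects (MAVEs) yield a continuous score per
variant; paired abundance and activity assays are each reduced to binary
high/low calls and combined into four classes:

* ``WT_like``            — high abundance, high activity
* ``total_loss``         — low abundance, low activity (stability-mediated)
* ``SBI``                — stable but inactive: high abundance, low activity,
                           the signature of a directly functional residue
* ``low_abundance_high_activity`` — low abundance, high activity

The per-assay cutoff is found by fitting the score distribution with a
three-component Gaussian mixture (the middle component absorbs
intermediate-effect variants) and taking the score at which the first and
last components' weighted densities intersect.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture


class VariantClass(str, enum.Enum):
    WT_LIKE = "WT_like"
    TOTAL_LOSS = "total_loss"
    SBI = "SBI"
    LOW_ABUNDANCE_HIGH_ACTIVITY = "low_abundance_high_activity"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed label ordering used throughout (classifier classes, reports).
CLASS_ORDER = tuple(c.value for c in VariantClass)


@dataclass
class GaussianMixtureFit:
    """Three-component 1-D Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("mixture sds must be positive")
        if not (np.diff(self.means) >= 0).all():
            raise ValueError("components must be sorted by mean")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


def fit_three_gaussians(
    scores,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    covariance_type: str = "tied",
) -> GaussianMixtureFit:
    """EM-fit a three-component Gaussian mixture to the score distribution.

    k-means initialised with ``n_init`` restarts (best log-likelihood kept);
    deterministic for a given seed.  Requires >= 30 finite scores and
    non-degenerate data.

    Components share one variance by default (``covariance_type='tied'``).
    The intersection threshold sits far out in both outer components' tails,
    where the crossing point is several times more sensitive to the fitted
    variances than to the means; tying the variance removes that instability
    while changing the threshold negligibly for well-separated modes.  Pass
    ``covariance_type='full'`` for per-component variances.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError("scores contain non-finite values")
    if x.size < 30:
        raise ValueError(f"need at least 30 scores to fit a mixture, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate score distribution (all values equal)")
    gm = GaussianMixture(
        n_components=3,
        covariance_type=covariance_type,
        n_init=n_init,
        init_params="kmeans",
        max_iter=max_iter,
        random_state=seed,
    ).fit(x.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.4f})"
        )
    order = np.argsort(gm.means_.ravel())
    if covariance_type == "tied":
        sds = np.full(3, float(np.sqrt(gm.covariances_.ravel()[0])))
    else:
        sds = np.sqrt(gm.covariances_.ravel()[order])
    return GaussianMixtureFit(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=sds,
        log_likelihood=float(gm.lower_bound_ * x.size),
        n_iter=int(gm.n_iter_),
        seed=seed,
    )


def intersection_threshold(fit: GaussianMixtureFit) -> float:
    """Score at which the first and last components' weighted densities cross.

    Solves w1 N(x; mu1, s1) = w3 N(x; mu3, s3) — a quadratic in x (linear when
    s1 = s3) — and returns the root strictly between the two component means,
    i.e. the decision boundary.  The middle component plays no role.
    """
    w1, w3 = fit.weights[0], fit.weights[2]
    m1, m3 = fit.means[0], fit.means[2]
    s1, s3 = fit.sds[0], fit.sds[2]
    if m1 == m3:
        raise ValueError("outer components have equal means; no threshold")
    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w3 - log s3 - (x-m3)^2/(2 s3^2)
    a = 1.0 / (2 * s3**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m3 / s3**2
    c = (
        m3**2 / (2 * s3**2)
        - m1**2 / (2 * s1**2)
        + np.log(w1 * s3 / (w3 * s1))
    )
    if np.isclose(a, 0.0, atol=1e-14):
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            raise ValueError(
                "no real intersection of outer components; set the threshold "
                "manually"
            )
        roots = np.array(
            [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
        )
    inside = roots[(roots > m1) & (roots < m3)]
    if inside.size == 0:
        raise ValueError(
            f"no intersection inside ({m1:.4g}, {m3:.4g}); set the threshold "
            "manually"
        )
    return float(inside[0])


def binarize(scores, threshold: float, higher_is_functional: bool = True) -> np.ndarray:
    """Reduce scores to 'high'/'low' calls against a threshold.

    ``higher_is_functional`` states the assay orientation (must be configured,
    never inferred).  Scores exactly at the threshold count as 'high'.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    x = np.asarray(scores, dtype=float)
    high = x >= threshold if higher_is_functional else x <= threshold
    return np.where(high, "high", "low")


_CLASS_MAP = {
    ("high", "high"): VariantClass.WT_LIKE,
    ("low", "low"): VariantClass.TOTAL_LOSS,
    ("high", "low"): VariantClass.SBI,
    ("low", "high"): VariantClass.LOW_ABUNDANCE_HIGH_ACTIVITY,
}


def combine_classes(abundance_call: str, activity_call: str) -> VariantClass:
    """Map paired (abundance, activity) binary calls to the four classes."""
    try:
        return _CLASS_MAP[(abundance_call, activity_call)]
    except KeyError:
        raise ValueError(
            f"calls must be 'high'/'low', got ({abundance_call!r}, "
            f"{activity_call!r})"
        ) from None


@dataclass
class MaveLabelling:
    """Labelled MAVE dataset plus the mixture fits and thresholds used."""

    data: pd.DataFrame
    abundance_fit: GaussianMixtureFit
    activity_fit: GaussianMixtureFit
    abundance_threshold: float
    activity_threshold: float

    def sidecar(self) -> dict:
        return {
            "abundance": {
                "threshold": self.abundance_threshold,
                "mixture": self.abundance_fit.to_dict(),
            },
            "activity": {
                "threshold": self.activity_threshold,
                "mixture": self.activity_fit.to_dict(),
            },
        }

    def write(self, csv_path, sidecar_path=None) -> None:
        self.data.to_csv(csv_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.sidecar(), fh, indent=2)


def label_mave(
    data: pd.DataFrame,
    seed: int = 0,
    abundance_higher_is_functional: bool = True,
    activity_higher_is_functional: bool = True,
) -> MaveLabelling:
    """Threshold both assays and assign each variant to one of four classes.

    ``data`` needs columns ``position, wt, mut, abundance_score,
    activity_score``; variants missing either score are excluded from
    labelling (kept in the output with class NaN).
    """
    required = {"position", "wt", "mut", "abundance_score", "activity_score"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"MAVE table missing columns {sorted(missing)}")
    dup = data.duplicated(subset=["position", "wt", "mut"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate variants in MAVE table"
        )
    out = data.copy()
    for col in ("abundance_call", "activity_call", "class"):
        out[col] = pd.Series(np.nan, index=out.index, dtype=object)
    ok = out["abundance_score"].notna() & out["activity_score"].notna()

    ab_fit = fit_three_gaussians(out.loc[ok, "abundance_score"], seed=seed)
    ac_fit = fit_three_gaussians(out.loc[ok, "activity_score"], seed=seed + 1)
    ab_thr = intersection_threshold(ab_fit)
    ac_thr = intersection_threshold(ac_fit)

    out.loc[ok, "abundance_call"] = binarize(
        out.loc[ok, "abundance_score"], ab_thr, abundance_higher_is_functional
    )
    out.loc[ok, "activity_call"] = binarize(
        out.loc[ok, "activity_score"], ac_thr, activity_higher_is_functional
    )
    out.loc[ok, "class"] = [
        combine_classes(a, b).value
        for a, b in zip(out.loc[ok, "abundance_call"], out.loc[ok, "activity_call"])
    ]
    return MaveLabelling(
        data=out,
        abundance_fit=ab_fit,
        activity_fit=ac_fit,
        abundance_threshold=ab_thr,
        activity_threshold=ac_thr,
    )
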