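"""Accuracy metrics over simulation replicates and derived genetic
parameters per posterior draw.

RMSE and MAE aggregate point estimates against the simulation truth
over replicates; relative versions divide by the NUTS-LKJ metric so the
baseline method scores exactly 1.0.  Derived parameters (heritability,
genetic and residual correlations) are computed per posterior draw and
then averaged -- never as ratios of averaged components.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateEstimates",
    "DerivedParams",
    "error_metrics",
    "derived_parameters",
    "ebv_metrics",
]

BASELINE_METHOD = "nuts-lkj"


@dataclass
class ReplicateEstimates:
    """Per-replicate point estimates plus the set of true parameter values.

    ``estimates`` needs columns: method, replicate, parameter, estimate.
    ``truth`` maps parameter label -> the value used in the simulation.
    """

    estimates: pd.DataFrame
    truth: dict[str, float]

    def __post_init__(self) -> None:
        required = {"method", "replicate", "parameter", "estimate"}
        missing = required - set(self.estimates.columns)
        if missing:
            raise ValueError(f"estimates frame lacks columns: {sorted(missing)}")
        if self.estimates.empty:
            raise ValueError("need at least one replicate estimate")


def error_metrics(
    est: ReplicateEstimates, baseline: str = BASELINE_METHOD
) -> pd.DataFrame:
    """RMSE and MAE per (method, parameter), with relative versions.

    RMSE = sqrt(mean_i (est_i - truth)^2), MAE = mean_i |est_i - truth|
    over the q replicates; relative metrics divide by the baseline
    method's value (so the baseline is exactly 1.0).  Errors out when a
    relative metric would divide by zero while the numerator is not zero.
    """
    df = est.estimates.copy()
    df["truth"] = df["parameter"].map(est.truth)
    if df["truth"].isna().any():
        bad = sorted(df.loc[df["truth"].isna(), "parameter"].unique())
        raise ValueError(f"no true value supplied for parameters: {bad}")
    df["err"] = df["estimate"] - df["truth"]
    grouped = df.groupby(["method", "parameter"])["err"]
    out = pd.DataFrame(
        {
            "rmse": grouped.apply(lambda e: float(np.sqrt(np.mean(e ** 2)))),
            "mae": grouped.apply(lambda e: float(np.mean(np.abs(e)))),
        }
    ).reset_index()
    if baseline in set(out["method"]):
        base = out[out["method"] == baseline].set_index("parameter")
        for metric in ("rmse", "mae"):
            rel = []
            for _, row in out.iterrows():
                b = float(base.loc[row["parameter"], metric])
                v = float(row[metric])
                if b == 0.0:
                    if v == 0.0:
                        rel.append(1.0)
                    else:
                        raise ValueError(
                            f"relative {metric} undefined for "
                            f"{row['parameter']}: baseline metric is zero"
                        )
                else:
                    rel.append(v / b)
            out[f"rel_{metric}"] = rel
    return out


@dataclass
class DerivedParams:
    """Per-draw heritabilities and correlations with posterior summaries."""

    h2: np.ndarray  # (k, t)
    r_a: np.ndarray  # (k, q) genetic correlations, row-wise lower triangle
    r_e: np.ndarray  # (k, q)

    @property
    def posterior_mean(self) -> dict[str, np.ndarray]:
        return {
            "h2": self.h2.mean(axis=0),
            "r_a": self.r_a.mean(axis=0),
            "r_e": self.r_e.mean(axis=0),
        }

    @property
    def posterior_sd(self) -> dict[str, np.ndarray]:
        return {
            "h2": self.h2.std(axis=0, ddof=1),
            "r_a": self.r_a.std(axis=0, ddof=1),
            "r_e": self.r_e.std(axis=0, ddof=1),
        }


def _offdiag_corr(C: np.ndarray) -> np.ndarray:
    t = C.shape[0]
    s = np.sqrt(np.diag(C))
    out = []
    for i in range(1, t):
        for j in range(i):
            out.append(C[i, j] / (s[i] * s[j]))
    return np.asarray(out)


def derived_parameters(G0_draws: np.ndarray, R0_draws: np.ndarray) -> DerivedParams:
    """Heritabilities and correlations for every posterior draw.

    Each draw must be symmetric positive definite; the offending draw
    index is reported otherwise.
    """
    G0_draws = np.asarray(G0_draws, dtype=float)
    R0_draws = np.asarray(R0_draws, dtype=float)
    if G0_draws.shape != R0_draws.shape or G0_draws.ndim != 3:
        raise ValueError("need matching (k, t, t) draw stacks for G0 and R0")
    k, t, _ = G0_draws.shape
    h2 = np.empty((k, t))
    q = t * (t - 1) // 2
    r_a = np.empty((k, q))
    r_e = np.empty((k, q))
    for i in range(k):
        for name, C in (("G0", G0_draws[i]), ("R0", R0_draws[i])):
            if np.linalg.eigvalsh(0.5 * (C + C.T))[0] <= 0:
                raise ValueError(f"draw {i}: {name} is not positive definite")
        dg = np.diag(G0_draws[i])
        dr = np.diag(R0_draws[i])
        h2[i] = dg / (dg + dr)
        r_a[i] = _offdiag_corr(G0_draws[i])
        r_e[i] = _offdiag_corr(R0_draws[i])
    return DerivedParams(h2=h2, r_a=r_a, r_e=r_e)


def ebv_metrics(a_true_test: np.ndarray, a_hat_test: np.ndarray) -> pd.DataFrame:
    """Per-trait Pearson accuracy and RMSE of estimated breeding values
    on the test animals (whose phenotypes were withheld from fitting)."""
    a_true_test = np.asarray(a_true_test, dtype=float)
    a_hat_test = np.asarray(a_hat_test, dtype=float)
    if a_true_test.shape != a_hat_test.shape or a_true_test.ndim != 2:
        raise ValueError("true and estimated EBV arrays must both be (n, t)")
    rows = []
    for j in range(a_true_test.shape[1]):
        x = a_true_test[:, j]
        y = a_hat_test[:, j]
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(
                f"trait {j}: zero variance, Pearson accuracy undefined"
            )
        rows.append(
            {
                "trait": j,
                "accuracy": float(np.corrcoef(x, y)[0, 1]),
                "rmse": float(np.sqrt(np.mean((x - y) ** 2))),
            }
        )
    return pd.DataFrame(rows)
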