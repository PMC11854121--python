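"""Neutral community model fit: occurrence frequency vs. mean relative
abundance.

The model predicts the probability that a taxon is detected in a local
community from its metacommunity relative abundance p, an effective
community size N and a migration probability m. In the beta-distribution
parameterisation, the stationary local frequency of a taxon is
Beta(N*m*p, N*m*(1-p)); the predicted occurrence frequency is the
probability that this frequency exceeds the detection limit d = 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .community_data import AsvTable

__all__ = [
    "NeutralFit",
    "occupancy_abundance",
    "predict_occurrence",
    "fit_neutral_model",
]

_NM_BOUNDS = (1e-3, 1e6)


@dataclass
class NeutralFit:
    """Fitted migration parameter with per-taxon predictions and bands."""

    m: float
    Nm: float
    N: float
    r2: float
    d: float
    conf: float
    taxa: pd.DataFrame
    """Per-taxon records: taxon_id, p, observed_freq, predicted_freq,
    lower, upper, partition (above/within/below)."""

    def partition_counts(self) -> dict[str, int]:
        c = self.taxa["partition"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("above", "within", "below")}

    def summary(self) -> str:
        return (
            f"m={self.m:.4g} Nm={self.Nm:.4g} N={self.N:.4g} "
            f"r2={self.r2:.4g} d={self.d:.3g}"
        )


def occupancy_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-taxon metacommunity mean relative abundance and occupancy.

    p_i is the mean over samples of within-sample relative abundance (so
    that sum_i p_i = 1); observed_freq_i is the fraction of samples in which
    the taxon is detected.
    """
    if table.mode != "counts":
        raise ValueError("occupancy_abundance expects a counts-mode table")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rel = table.relative_matrix()  # raises on empty samples
    p = rel.mean(axis=1)
    freq = (table.counts > 0).mean(axis=1)
    return pd.DataFrame(
        {"taxon_id": table.taxon_ids, "p": p, "observed_freq": freq}
    )


def predict_occurrence(p, Nm: float, d: float):
    """Predicted occurrence frequency for metacommunity abundance ``p``.

    Returns 1 - BetaCDF(d; Nm*p, Nm*(1-p)), the stationary probability that
    the local frequency exceeds the detection limit. Accepts scalars or
    arrays; p must lie strictly inside (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must lie in (0, 1)")
    out = beta_dist.sf(d, Nm * p, Nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def fit_neutral_model(table: AsvTable, conf: float = 0.95) -> NeutralFit:
    """Fit the neutral model to a counts-mode table.

    N is the arithmetic mean sample total and d = 1/N the single-read
    detection limit. Nm is estimated by bounded least squares of predicted
    vs. observed occurrence frequency over taxa (frequency scale, no
    transform); m = Nm / N. The prediction band holds exact binomial
    quantiles of occupancy at ``n_samples`` trials around the predicted
    frequency, and each taxon is labelled above/within/below the band.
    """
    occ = occupancy_abundance(table)
    n_samples = table.n_samples
    N = float(table.sample_totals().mean())
    d = 1.0 / N

    # clip p away from the degenerate beta endpoints; a taxon with p == 1
    # cannot occur in a multi-taxon table
    p = np.clip(occ["p"].to_numpy(), 1e-12, 1 - 1e-12)
    freq = occ["observed_freq"].to_numpy()

    def residuals(log_nm: np.ndarray) -> np.ndarray:
        return predict_occurrence(p, float(np.exp(log_nm[0])), d) - freq

    x0 = np.log(0.1 * N)
    lo, hi = np.log(_NM_BOUNDS[0]), np.log(_NM_BOUNDS[1])
    x0 = float(np.clip(x0, lo + 1e-6, hi - 1e-6))
    res = optimize.least_squares(
        residuals, x0=[x0], bounds=([lo], [hi]), method="trf"
    )
    if not res.success:
        raise RuntimeError(f"neutral-model fit failed: {res.message}")
    log_nm = float(res.x[0])
    if log_nm - lo < 1e-8 or hi - log_nm < 1e-8:
        raise RuntimeError(
            f"fitted Nm={np.exp(log_nm):.3g} is at the bound "
            f"{_NM_BOUNDS}; data are not informative for the model"
        )
    Nm = float(np.exp(log_nm))

    pred = predict_occurrence(p, Nm, d)
    ss_res = float(np.sum((freq - pred) ** 2))
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    alpha = 1.0 - conf
    lower = binom.ppf(alpha / 2, n_samples, pred) / n_samples
    upper = binom.ppf(1 - alpha / 2, n_samples, pred) / n_samples
    lower = np.minimum(lower, pred)
    upper = np.maximum(upper, pred)

    partition = np.where(
        freq > upper, "above", np.where(freq < lower, "below", "within")
    )
    taxa = pd.DataFrame(
        {
            "taxon_id": occ["taxon_id"],
            "p": occ["p"],
            "observed_freq": freq,
            "predicted_freq": pred,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        }
    )
    return NeutralFit(
        m=Nm / N, Nm=Nm, N=N, r2=r2, d=d, conf=conf, taxa=taxa
    )
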