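"""Doublet/debris removal via a two-component Gaussian mixture on QC channels.

The seven QC channels are mean-variance scaled, a two-component
full-covariance Gaussian mixture is fit by EM, events are assigned to
components by maximum posterior, and the component with the *smaller
mixing weight* is discarded wholesale as doublets and debris.  The fit is
done per sample (one individual, one condition) by default, since
acquisition artifacts are sample-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .panel import EventTable

__all__ = [
    "GmmFit",
    "CleanupReport",
    "ZeroVarianceError",
    "scale_qc",
    "fit_gmm2",
    "filter_events",
    "clean_sample",
]

RIDGE = 1e-6  # covariance regularization


class ZeroVarianceError(ValueError):
    def __init__(self, channels: list[str]):
        self.channels = channels
        super().__init__(f"zero-variance QC channel(s): {', '.join(channels)}")


@dataclass
class GmmFit:
    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2, q)
    covariances: np.ndarray  # (2, q, q)
    converged: bool
    loglik_trace: list[float]
    scaling: tuple[np.ndarray, np.ndarray]  # per-channel (mean, sd)

    @property
    def smaller_component(self) -> int:
        return int(np.argmin(self.weights))


@dataclass
class CleanupReport:
    n_total: int
    n_kept: int
    n_discarded: int
    component_counts: tuple[int, int]
    weights: tuple[float, float]
    discarded_component: int
    converged: bool
    low_weight_warning: bool = False
    individual_id: str = ""
    condition: str = ""
    keep_mask: np.ndarray | None = None  # aligned with the input table; not serialized

    def to_dict(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "condition": self.condition,
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "n_discarded": self.n_discarded,
            "component_counts": list(self.component_counts),
            "weights": list(self.weights),
            "discarded_component": self.discarded_component,
            "converged": self.converged,
            "low_weight_warning": self.low_weight_warning,
        }


def scale_qc(table: EventTable) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Mean-variance scale the QC channels (population sd, ddof=0)."""
    qc = table.qc_matrix()
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0)
    zero = sd == 0
    if zero.any():
        names = [n for n, z in zip(table.panel.qc_names, zero) if z]
        raise ZeroVarianceError(names)
    return (qc - mean) / sd, (mean, sd)


def fit_gmm2(
    scaled: np.ndarray, seed: int = 0, max_iter: int = 200, tol: float = 1e-6
) -> GmmFit:
    """EM fit of a 2-component full-covariance Gaussian mixture.

    k-means initialization under ``seed``; one EM step per outer iteration
    so the per-event mean log-likelihood trace is recorded; stops when the
    relative log-likelihood change falls below ``tol``.
    """
    scaled = np.asarray(scaled, dtype=float)
    if not np.isfinite(scaled).all():
        raise ValueError("QC matrix contains non-finite values")
    n, q = scaled.shape
    if n < 2 * q + 2:
        raise ValueError(f"need at least {2 * q + 2} events to fit the mixture, got {n}")

    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        reg_covar=RIDGE,
        init_params="kmeans",
        random_state=seed,
        max_iter=1,
        warm_start=True,
        tol=0.0,
        n_init=1,
    )
    trace: list[float] = []
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(scaled)
            ll = float(gm.score(scaled))
            if trace:
                prev = trace[-1]
                if (ll - prev) < tol * max(1.0, abs(ll)):
                    trace.append(ll)
                    converged = True
                    break
            trace.append(ll)

    scaling_mean = np.zeros(q)
    scaling_sd = np.ones(q)
    return GmmFit(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        converged=converged,
        loglik_trace=trace,
        scaling=(scaling_mean, scaling_sd),
    )


def _log_gaussian(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    q = x.shape[1]
    chol = cho_factor(cov, lower=True)
    diff = x - mean
    solved = cho_solve(chol, diff.T).T
    maha = np.einsum("ij,ij->i", diff, solved)
    logdet = 2.0 * np.log(np.diag(chol[0])).sum()
    return -0.5 * (q * np.log(2.0 * np.pi) + logdet + maha)


def posterior(scaled: np.ndarray, fit: GmmFit) -> np.ndarray:
    """Component posterior probabilities, (n, 2)."""
    logp = np.column_stack(
        [
            np.log(fit.weights[k]) + _log_gaussian(scaled, fit.means[k], fit.covariances[k])
            for k in range(2)
        ]
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


LOW_WEIGHT_FLOOR = 1e-3  # smaller weights than this are still removed, but flagged


def filter_events(
    table: EventTable, fit: GmmFit, scaled: np.ndarray | None = None
) -> tuple[EventTable, CleanupReport]:
    """Discard all events MAP-assigned to the smaller-weight component.

    If the two weights are exactly equal the tie is broken by keeping the
    component with the larger total posterior mass.
    """
    if scaled is None:
        qc = table.qc_matrix()
        mean, sd = fit.scaling
        # scaling recorded as identity when fit was given a pre-scaled matrix
        scaled = (qc - mean) / np.where(sd == 0, 1.0, sd)
    post = posterior(scaled, fit)
    assign = post.argmax(axis=1)

    if fit.weights[0] == fit.weights[1]:
        mass = post.sum(axis=0)
        discard = int(np.argmin(mass))
    else:
        discard = fit.smaller_component

    keep_mask = assign != discard
    counts = (int((assign == 0).sum()), int((assign == 1).sum()))
    kept = table.subset(keep_mask)
    report = CleanupReport(
        n_total=table.n_events,
        n_kept=kept.n_events,
        n_discarded=table.n_events - kept.n_events,
        component_counts=counts,
        weights=(float(fit.weights[0]), float(fit.weights[1])),
        discarded_component=discard,
        converged=fit.converged,
        low_weight_warning=bool(fit.weights.min() < LOW_WEIGHT_FLOOR),
        individual_id=table.individual_id,
        condition=table.condition,
        keep_mask=keep_mask,
    )
    return kept, report


def clean_sample(
    table: EventTable, seed: int = 0, max_iter: int = 200, tol: float = 1e-6
) -> tuple[EventTable, CleanupReport, GmmFit]:
    """Scale, fit, and filter one sample (individual x condition).

    The report carries the boolean keep mask aligned with the input table.
    """
    scaled, (mean, sd) = scale_qc(table)
    fit = fit_gmm2(scaled, seed=seed, max_iter=max_iter, tol=tol)
    fit.scaling = (mean, sd)
    kept, report = filter_events(table, fit, scaled=scaled)
    return kept, report, fit
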