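"""Reference-based cell-type deconvolution by constrained least squares.

Bulk blood methylation is modelled per sample as a mixture of cell-type
reference profiles, ``b ~ R pi``, and the proportions ``pi`` are recovered by
non-negative least squares on a subset of cell-type-discriminating probes —
the constrained-projection approach introduced by Houseman and used by
``minfi::estimateCellCounts`` for the standard six adult leukocyte types
(granulocytes, CD4+ T, CD8+ T, B cells, NK cells, monocytes).

The default solves with non-negativity only, matching the original
projection; an optional simplex constraint renormalises the solution to sum
to one.  Any column subset of the reference may be used (some cohorts adjust
for five of the six types, omitting granulocytes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .simcohort import CellReference

__all__ = ["ProportionEstimate", "select_discriminating_sites", "estimate_cell_proportions"]


@dataclass
class ProportionEstimate:
    """Estimated cell proportions per sample with per-sample residual norms."""

    proportions: pd.DataFrame  # samples x K
    residual_norm: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return self.proportions


def select_discriminating_sites(reference: CellReference, t: int) -> np.ndarray:
    """Pick the ``t`` probes that best separate the cell types.

    Probes are ranked by between-type range of the reference profile and
    balanced per type between hypermethylated markers (the type's own value is
    the maximum) and hypomethylated markers (the minimum), t/2 of each
    overall, rounded so that hyper gets the extra slot when ``t`` is odd.
    Ties break by probe_id order, so the selection is invariant to the row
    order of the reference.
    """
    m = reference.n_probes
    if t > m:
        raise ValueError(f"requested t={t} sites but the reference has only {m} probes")
    prof = reference.profiles
    order = np.argsort(reference.probe_ids, kind="stable")
    prof_sorted = prof[order]
    rng_ = prof_sorted.max(axis=1) - prof_sorted.min(axis=1)
    mean_others = (prof_sorted.sum(axis=1, keepdims=True) - prof_sorted) / (prof.shape[1] - 1)
    is_hyper = prof_sorted.max(axis=1) > mean_others.max(axis=1)  # own max above the rest
    n_hyper = t // 2 + t % 2
    n_hypo = t // 2

    def top(mask: np.ndarray, n: int) -> np.ndarray:
        idx = np.flatnonzero(mask)
        ranked = idx[np.argsort(-rng_[idx], kind="stable")]
        return ranked[:n]

    hyper_sel = top(is_hyper, n_hyper)
    hypo_sel = top(~is_hyper, n_hypo)
    chosen = np.concatenate([hyper_sel, hypo_sel])
    if len(chosen) < t:  # one side exhausted; fill from the other
        rest = np.setdiff1d(np.arange(m), chosen)
        extra = rest[np.argsort(-rng_[rest], kind="stable")][: t - len(chosen)]
        chosen = np.concatenate([chosen, extra])
    ids = reference.probe_ids[order][chosen]
    return np.sort(ids)


def estimate_cell_proportions(
    beta: pd.DataFrame,
    reference: CellReference,
    sites: np.ndarray | list[str] | None = None,
    constraint: str = "nonneg",
) -> ProportionEstimate:
    """Estimate per-sample cell proportions by constrained projection.

    Per sample, solves ``min ||R_s pi - b_s||^2`` subject to ``pi >= 0``
    (``constraint='nonneg'``, the default) or additionally renormalised to
    the simplex (``constraint='simplex'``).  Deterministic.
    """
    if constraint not in ("nonneg", "simplex"):
        raise ValueError("constraint must be 'nonneg' or 'simplex'")
    ref_df = reference.to_frame()
    if sites is None:
        sites = np.asarray(beta.columns)
    sites = np.asarray(sites)
    missing = [s for s in sites if s not in beta.columns or s not in ref_df.index]
    if missing:
        raise ValueError(f"sites absent from beta or reference: {missing[:5]}")
    r = ref_df.loc[sites].to_numpy()  # (t, K)
    if np.linalg.matrix_rank(r) < r.shape[1]:
        warnings.warn(
            "reference columns are collinear on the selected sites; "
            "returning the least-norm non-negative solution",
            stacklevel=2,
        )
    b = beta.loc[:, sites].to_numpy()  # (n, t)
    k = r.shape[1]
    if constraint == "simplex":
        # enforce sum-to-one through a heavily weighted extra equation, then
        # renormalise the (already ~1e-12 accurate) sum exactly
        w_eq = 1e6
        r_solve = np.vstack([r, w_eq * np.ones((1, k))])
    else:
        r_solve = r
    out = np.empty((b.shape[0], k))
    resid = np.empty(b.shape[0])
    for i in range(b.shape[0]):
        rhs = np.concatenate([b[i], [w_eq]]) if constraint == "simplex" else b[i]
        out[i], _ = nnls(r_solve, rhs)
        resid[i] = np.linalg.norm(r @ out[i] - b[i])
    if constraint == "simplex":
        sums = out.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("all-zero solution cannot be renormalised to the simplex")
        out = out / sums[:, None]
    props = pd.DataFrame(out, index=beta.index, columns=list(reference.cell_names))
    return ProportionEstimate(props, pd.Series(resid, index=beta.index, name="residual_norm"))
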