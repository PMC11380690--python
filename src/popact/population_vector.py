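"""Trial-by-trial population vector correlation (PVC).

For one session and epoch, the population vector of a trial is the per-cell
mean response over that epoch (traces baselined per trial to the mean of the
2 s pre-stimulus period). Pearson correlations between all trial pairs form
an N-by-N matrix whose mean off-diagonal value summarizes the session; phase
comparisons use a linear mixed model with a random intercept per mouse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .preprocess import TrialEpochTensor

logger = logging.getLogger("popact")

PVC_BASELINE = "pre-stim-2s"


@dataclass
class PopulationVectorSet:
    vectors: np.ndarray       # (trials, cells)
    epoch: str
    trial_filter: str
    pvc_matrix: np.ndarray    # (trials, trials)
    trial_index: np.ndarray


@dataclass
class PhaseComparison:
    estimate: float
    se: float
    p: float
    method: str               # "lmm" or "ols-fallback"
    table: pd.DataFrame


def build_population_vectors(
    tensor: TrialEpochTensor,
    trial_mask: np.ndarray | None = None,
    trial_filter: str = "all",
) -> PopulationVectorSet:
    """Per-trial mean-epoch vectors and their trial-by-trial correlation.

    Requires the 2 s pre-stimulus baseline convention. Cells with zero
    variance across the filtered trials are dropped (Pearson undefined).
    """
    if tensor.baseline != PVC_BASELINE:
        raise ValueError(
            f"PVC requires baseline '{PVC_BASELINE}', got '{tensor.baseline}'"
        )
    vectors = tensor.values.mean(axis=2)  # trials x cells
    trial_index = np.asarray(tensor.trial_index)
    if trial_mask is not None:
        trial_mask = np.asarray(trial_mask, dtype=bool)
        vectors = vectors[trial_mask]
        trial_index = trial_index[trial_mask]
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 trials after filtering")
    keep = vectors.std(axis=0) > 0
    if not keep.all():
        logger.info("PVC: dropped %d zero-variance cells", int((~keep).sum()))
    vectors = vectors[:, keep]
    pvc = np.corrcoef(vectors)
    return PopulationVectorSet(vectors, tensor.window, trial_filter, pvc, trial_index)


def session_mean_pvc(pvs: PopulationVectorSet | np.ndarray) -> float:
    """Mean Pearson r over all distinct trial pairs (strict upper triangle)."""
    m = pvs.pvc_matrix if isinstance(pvs, PopulationVectorSet) else np.asarray(pvs)
    iu = np.triu_indices(m.shape[0], k=1)
    return float(m[iu].mean())


def compare_phases_lmm(
    session_means, phase_labels, mouse_ids, expert_label: str = "expert"
) -> PhaseComparison:
    """Random-intercept mixed model of session-mean PVC on learning phase.

    Fixed effect: phase (expert vs naive); random intercept: mouse. Fitted by
    REML; the phase effect is tested with a large-sample Wald z. On a
    singular / non-converged fit, falls back to OLS and says so.
    """
    df = pd.DataFrame({
        "value": np.asarray(session_means, dtype=float),
        "phase": list(phase_labels),
        "mouse": list(mouse_ids),
    })
    if df["mouse"].nunique() < 2:
        raise ValueError("need at least 2 mice")
    if df["phase"].nunique() < 2:
        raise ValueError("both phases must be represented")
    df["is_expert"] = (df["phase"] == expert_label).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("value ~ is_expert", df, groups=df["mouse"])
            fit = model.fit(reml=True)
        est = float(fit.params["is_expert"])
        se = float(fit.bse["is_expert"])
        p = float(fit.pvalues["is_expert"])
        if not np.isfinite(se) or se == 0:
            raise ValueError("singular mixed-model fit")
        method = "lmm"
    except Exception as exc:  # singular fit or convergence failure
        logger.warning("mixed model failed (%s); falling back to OLS", exc)
        X = sm.add_constant(df["is_expert"])
        fit = sm.OLS(df["value"], X).fit()
        est = float(fit.params["is_expert"])
        se = float(fit.bse["is_expert"])
        p = float(fit.pvalues["is_expert"])
        method = "ols-fallback"
    return PhaseComparison(estimate=est, se=se, p=p, method=method, table=df)


def stratify_by_anticipatory_licking(
    pvs: PopulationVectorSet,
    lick_counts: np.ndarray,
    min_trials: int = 6,
):
    """Split a (Hit-trial) vector set by presence of anticipatory licking.

    Returns ``(with_set, without_set)`` or None when the session fails the
    "> min_trials in each stratum" inclusion rule.
    """
    counts = np.asarray(lick_counts)
    if counts.shape[0] != pvs.vectors.shape[0]:
        raise ValueError("lick counts must align with trials")
    with_mask = counts > 0
    n_with, n_without = int(with_mask.sum()), int((~with_mask).sum())
    if n_with <= min_trials or n_without <= min_trials:
        logger.info(
            "anticipatory stratification: session excluded (%d with / %d without)",
            n_with, n_without,
        )
        return None

    def subset(mask):
        v = pvs.vectors[mask]
        return PopulationVectorSet(
            v, pvs.epoch, pvs.trial_filter + ("+lick" if mask is with_mask else "-lick"),
            np.corrcoef(v), pvs.trial_index[mask],
        )

    return subset(with_mask), subset(~with_mask)


def remove_cells_control(
    pvs: PopulationVectorSet,
    remove_idx,
    n_random_shuffles: int = 30,
    seed: int = 0,
):
    """Mean PVC after targeted cell removal vs random same-size removals.

    Returns ``(reduced_mean_r, shuffle_means)`` where the shuffle array holds
    the mean PVC of ``n_random_shuffles`` random removals of the same size.
    """
    remove_idx = np.asarray(remove_idx, dtype=int)
    n_cells = pvs.vectors.shape[1]
    if remove_idx.size >= n_cells:
        raise ValueError("removal would empty the population")

    def mean_after_removal(idx):
        keep = np.setdiff1d(np.arange(n_cells), idx)
        v = pvs.vectors[:, keep]
        v = v[:, v.std(axis=0) > 0]
        return session_mean_pvc(np.corrcoef(v))

    reduced = mean_after_removal(remove_idx)
    rng = np.random.default_rng(seed)
    shuffles = np.array([
        mean_after_removal(rng.choice(n_cells, size=remove_idx.size, replace=False))
        for _ in range(n_random_shuffles)
    ])
    return reduced, shuffles
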