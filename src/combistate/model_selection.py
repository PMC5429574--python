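"""Two-stage training protocol: ensemble fit, BIC selection, pruning, refit.

Several HMMs are trained from independent random initializations; the model
with the lowest BIC is kept.  States called in very few bins (below a fraction
of the average per-state call count) are then removed, their transition mass
redistributed to the surviving states, and the pruned model is retrained for a
second, shorter round to produce the final segmentation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm import CombinatorialHMM, TrainingTrace, floor_normalize, _as_obs

DEFAULT_N_MODELS = 5
DEFAULT_N_ITER = 300
DEFAULT_N_ITER_REFINE = 100
DEFAULT_PRUNE_FRAC = 0.05


@dataclass
class EnsembleResult:
    """Independently initialized trained models with their BIC scores."""

    models: list[CombinatorialHMM]
    traces: list[TrainingTrace]
    bics: np.ndarray
    seeds: list[int]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.bics))

    @property
    def best_model(self) -> CombinatorialHMM:
        return self.models[self.best_index]


def train_ensemble(sequences, n_states: int = 25,
                   n_models: int = DEFAULT_N_MODELS,
                   n_iter: int = DEFAULT_N_ITER,
                   base_seed: int = 0) -> EnsembleResult:
    """Train ``n_models`` HMMs with seeds base_seed..base_seed+n_models-1.

    Each model runs ``n_iter`` Baum-Welch iterations from its own random
    initialization; BIC is evaluated on the training sequences.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    models, traces, bics, seeds = [], [], [], []
    for k in range(n_models):
        seed = base_seed + k
        model = CombinatorialHMM(n_states=n_states, n_iter=n_iter,
                                 random_state=seed)
        model.fit(sequences)
        models.append(model)
        traces.append(model.history_)
        bics.append(model.bic(sequences))
        seeds.append(seed)
    return EnsembleResult(models=models, traces=traces,
                          bics=np.asarray(bics), seeds=seeds)


def find_infrequent_states(paths: Sequence[np.ndarray], n_states: int,
                           threshold_frac: float = DEFAULT_PRUNE_FRAC
                           ) -> set[int]:
    """States called in fewer bins than ``threshold_frac`` of the average.

    The average is total bins / n_states (over all states, including empty
    ones); a state is flagged iff its call count is strictly below
    ``threshold_frac * average``.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    paths = list(paths)
    if not paths or all(len(p) == 0 for p in paths):
        raise ValueError("no state calls supplied")
    counts = np.zeros(n_states, dtype=np.int64)
    for p in paths:
        counts += np.bincount(np.asarray(p, dtype=np.int64), minlength=n_states)
    average = counts.sum() / n_states
    return {int(s) for s in np.nonzero(counts < threshold_frac * average)[0]}


def prune_states(model: CombinatorialHMM, remove: set[int],
                 redistribute: str = "uniform") -> CombinatorialHMM:
    """Drop states, redistributing their transition and initial mass.

    Surviving states keep their emission rows unchanged.  With
    ``redistribute="uniform"`` (default) the mass each surviving row sent to
    removed states is split equally among the surviving columns; with
    ``"proportional"`` it is spread in proportion to the surviving entries.
    """
    remove = {int(s) for s in remove}
    keep = [s for s in range(model.n_states) if s not in remove]
    if not keep:
        raise ValueError("cannot remove all states")
    if bad := remove - set(range(model.n_states)):
        raise ValueError(f"states not in model: {sorted(bad)}")
    keep_idx = np.asarray(keep)
    n_keep = len(keep)

    def _redistribute(vec: np.ndarray) -> np.ndarray:
        kept = vec[keep_idx]
        lost = vec.sum() - kept.sum()
        if redistribute == "uniform":
            out = kept + lost / n_keep
        elif redistribute == "proportional":
            out = kept * (vec.sum() / kept.sum())
        else:
            raise ValueError(f"unknown redistribute mode {redistribute!r}")
        return out / out.sum()

    startprob = _redistribute(model.startprob_)
    transmat = np.vstack([_redistribute(model.transmat_[i]) for i in keep])
    emissionprob = model.emissionprob_[keep_idx]
    emissionprob = emissionprob / emissionprob.sum(axis=1, keepdims=True)
    return CombinatorialHMM.from_params(startprob, transmat, emissionprob,
                                        floor=model.floor)


def refine(model: CombinatorialHMM, sequences,
           n_iter: int = DEFAULT_N_ITER_REFINE
           ) -> tuple[CombinatorialHMM, TrainingTrace]:
    """Retrain a pruned model for a second, shorter Baum-Welch round."""
    out = CombinatorialHMM.from_params(
        model.startprob_, model.transmat_, model.emissionprob_, floor=model.floor)
    out.n_iter = n_iter
    out.fit(sequences, warm_start=True)
    return out, out.history_


@dataclass
class TwoStageResult:
    """Full protocol output: ensemble, pruning report and final model."""

    ensemble: EnsembleResult
    pruned_states: set[int]
    prune_report: pd.DataFrame
    model: CombinatorialHMM
    refine_trace: TrainingTrace


def fit_two_stage(sequences, n_states: int = 25,
                  n_models: int = DEFAULT_N_MODELS,
                  n_iter: int = DEFAULT_N_ITER,
                  n_iter_refine: int = DEFAULT_N_ITER_REFINE,
                  prune_frac: float = DEFAULT_PRUNE_FRAC,
                  base_seed: int = 0) -> TwoStageResult:
    """Ensemble train -> select by BIC -> decode -> prune once -> retrain.

    Pruning is applied exactly once; call counts come from Viterbi decoding
    of the selected model over all training sequences.
    """
    ensemble = train_ensemble(sequences, n_states=n_states, n_models=n_models,
                              n_iter=n_iter, base_seed=base_seed)
    best = ensemble.best_model
    obs_list = _as_obs(sequences)
    paths = [best.predict(o) for o in obs_list]
    infrequent = find_infrequent_states(paths, n_states, prune_frac)
    counts = np.zeros(n_states, dtype=np.int64)
    for p in paths:
        counts += np.bincount(p, minlength=n_states)
    threshold = prune_frac * counts.sum() / n_states
    report = pd.DataFrame({
        "state": np.arange(n_states),
        "call_count": counts,
        "threshold": threshold,
        "removed": [s in infrequent for s in range(n_states)],
    })
    pruned = prune_states(best, infrequent) if infrequent else best
    final, trace = refine(pruned, sequences, n_iter=n_iter_refine)
    return TwoStageResult(ensemble=ensemble, pruned_states=infrequent,
                          prune_report=report, model=final, refine_trace=trace)
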