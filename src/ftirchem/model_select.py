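"""Two-stage model selection over the factorial configuration grid.

Stage 1 ("screen") evaluates every (normalization, scaling, number of
components) cell of a PLS-DA grid on the full data: fit, cross-validated
Q2Y, and a response-permutation test; per normalization method the valid
cell with the best Q2Y advances.  Stage 2 ("vip_sweep") splits off one
analytical replicate per biological sample as a test set, computes VIP on
a training-only fit, refits on the variables above each cutoff, and
records RMSEE (training), RMSEP (test) and permutation intercepts
(training).  The winner is the valid candidate with the lowest RMSEP.

All preprocessing here is strictly per-sample (row-wise normalization and
filtering), so preprocessing the full set introduces no train/test
leakage; every fitted statistic (scaling, VIP, weights) uses training
rows only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import SpectrumSet, SpectrumError
from .preprocess import PreprocessConfig, run_preprocess
from .chemometrics import (
    PLSModel, fit_pls_raw, q2y, rmsee, rmsep, rmse_to_months,
    vip_scores, select_by_vip, dummy_code, FitError,
)
from .validation import permutation_test, is_valid_model

#: Normalization-axis names and the preprocessing recipe each denotes.
NORMALIZATION_CONFIGS = {
    "area": PreprocessConfig(method="area", derivative_order=0),
    "minmax": PreprocessConfig(method="minmax", derivative_order=0),
    "vector_d1": PreprocessConfig(method="vector", derivative_order=1),
    "vector_d2": PreprocessConfig(method="vector", derivative_order=2),
}


@dataclass
class GridSpec:
    """Axes of the factorial model-selection grid."""

    normalizations: tuple = ("area", "minmax", "vector_d1", "vector_d2")
    scalings: tuple = ("uv", "pareto")
    component_counts: tuple = (1, 2, 3)
    vip_cutoffs: tuple = (0.5, 0.7, 1.0, 1.3, 1.5)
    test_replicate_index: int = 6
    n_permutations: int = 100
    n_folds: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.normalizations and self.scalings and self.component_counts):
            raise ValueError("grid axes must be non-empty")
        for norm in self.normalizations:
            if norm not in NORMALIZATION_CONFIGS:
                raise ValueError(f"unknown normalization axis value {norm!r}")
        if any(c < 0 for c in self.vip_cutoffs):
            raise ValueError("VIP cutoffs must be non-negative")
        self.vip_cutoffs = tuple(sorted(self.vip_cutoffs))
        if not 1 <= self.test_replicate_index <= 6:
            raise ValueError("test_replicate_index must be in 1..6")


@dataclass
class ModelCandidate:
    """One evaluated grid cell (screening or VIP-sweep stage)."""

    normalization: str
    scaling: str
    n_components: int
    stage: str                        # "screen" | "vip_sweep"
    vip_cutoff: float | None = None
    retained_variable_count: int | None = None
    r2y: float | None = None
    q2y: float | None = None
    rmsee: float | None = None
    rmsep: float | None = None
    r2y_intercept: float | None = None
    q2y_intercept: float | None = None
    valid: bool = False
    feasible: bool = True
    reason: str | None = None
    model: PLSModel | None = None
    selected_wavenumbers: np.ndarray | None = None

    def row(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("model", "selected_wavenumbers")}
        return d


def split_replicates(s: SpectrumSet, test_replicate_index: int
                     ) -> tuple[SpectrumSet, SpectrumSet]:
    """Hold out one analytical replicate per biological sample.

    Returns ``(train, test)``: the test set contains exactly the rows with
    ``replicate_index == test_replicate_index``; training is the rest.
    """
    rep = s.metadata.get("replicate_index")
    if rep is None or rep.isna().any():
        missing = s.metadata.loc[rep.isna() if rep is not None else slice(None),
                                 "sample_id"].tolist() if rep is not None \
            else s.metadata["sample_id"].tolist()
        raise SpectrumError(f"replicate_index missing for samples {missing[:10]}")
    rep = rep.astype(int)
    if test_replicate_index not in set(rep):
        raise ValueError(
            f"test_replicate_index {test_replicate_index} not present "
            f"(have {sorted(set(rep))})")
    test_mask = (rep == test_replicate_index).to_numpy()
    return s.select_samples(~test_mask), s.select_samples(test_mask)


def _labels_for(s: SpectrumSet, label_field: str) -> np.ndarray:
    col = s.metadata.get(label_field)
    if col is None or col.isna().any():
        raise ValueError(f"metadata field {label_field!r} missing or incomplete")
    return col.to_numpy()


def screen_configurations(s: SpectrumSet, labels: Sequence, grid: GridSpec,
                          preprocessed: dict[str, SpectrumSet] | None = None
                          ) -> list[ModelCandidate]:
    """Stage 1: evaluate every (normalization, scaling, A) PLS-DA cell on
    the full data with fit, Q2Y, and permutation intercepts."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("screening needs at least 2 classes")
    if preprocessed is None:
        preprocessed = preprocess_all(s, grid.normalizations)
    candidates: list[ModelCandidate] = []
    for norm in grid.normalizations:
        prep = preprocessed.get(norm)
        if isinstance(prep, Exception):
            for scaling in grid.scalings:
                for A in grid.component_counts:
                    candidates.append(ModelCandidate(
                        norm, scaling, A, "screen", feasible=False,
                        reason=f"preprocessing failed: {prep}"))
            continue
        X = prep.intensities
        Y, classes = dummy_code(labels)
        for scaling in grid.scalings:
            for A in grid.component_counts:
                try:
                    model = fit_pls_raw(X, Y, A, scaling=scaling,
                                        variable_ids=prep.wavenumbers,
                                        class_labels=classes)
                    q2 = q2y(X, Y, A, n_folds=grid.n_folds, scaling=scaling)
                    perm = permutation_test(
                        X, Y, A, n_permutations=grid.n_permutations,
                        seed=_cell_seed(grid.seed, norm, scaling, A),
                        scaling=scaling, n_folds=grid.n_folds)
                except (FitError, ValueError) as exc:
                    candidates.append(ModelCandidate(
                        norm, scaling, A, "screen", feasible=False,
                        reason=str(exc)))
                    continue
                model.q2y_cum = q2
                candidates.append(ModelCandidate(
                    norm, scaling, A, "screen",
                    retained_variable_count=X.shape[1],
                    r2y=model.r2y_cum, q2y=q2,
                    r2y_intercept=perm.r2y_intercept,
                    q2y_intercept=perm.q2y_intercept,
                    valid=perm.valid, model=model,
                    selected_wavenumbers=prep.wavenumbers))
    return candidates


def preprocess_all(s: SpectrumSet, normalizations: Sequence[str]
                   ) -> dict[str, SpectrumSet]:
    """Run every normalization recipe once; failures stored as exceptions
    so a bad cell marks itself infeasible instead of aborting the run."""
    out: dict[str, SpectrumSet] = {}
    for norm in normalizations:
        try:
            out[norm] = run_preprocess(s, NORMALIZATION_CONFIGS[norm])
        except (SpectrumError, ValueError) as exc:  # recorded, not raised
            out[norm] = exc  # type: ignore[assignment]
    return out


def _cell_seed(base: int, norm: str, scaling: str, A: int, extra: int = 0) -> int:
    # process-independent hash: builtin hash() is randomized per interpreter
    h = zlib.crc32(f"{norm}|{scaling}|{A}|{extra}".encode()) % 100_000
    return (int(base) * 100_000 + h) % (2 ** 31 - 1)


def pick_screen_winners(candidates: list[ModelCandidate]) -> list[ModelCandidate]:
    """Per normalization method, the valid screen cell with the highest
    Q2Y (ties: higher R2Y, then fewer components)."""
    winners = []
    for norm in dict.fromkeys(c.normalization for c in candidates):
        valid = [c for c in candidates
                 if c.normalization == norm and c.feasible and c.valid]
        if not valid:
            continue
        winners.append(max(valid, key=lambda c: (c.q2y, c.r2y, -c.n_components)))
    return winners


def vip_sweep(s: SpectrumSet, labels: Sequence,
              screened: list[ModelCandidate], grid: GridSpec,
              preprocessed: dict[str, SpectrumSet] | None = None
              ) -> list[ModelCandidate]:
    """Stage 2: per screened configuration and VIP cutoff, train-only VIP
    selection, PLSR refit on retained variables, and split metrics."""
    labels = np.asarray(labels)
    if preprocessed is None:
        preprocessed = preprocess_all(s, {c.normalization for c in screened})
    out: list[ModelCandidate] = []
    for cand in screened:
        prep = preprocessed[cand.normalization]
        if isinstance(prep, Exception):
            continue
        train, test = split_replicates(prep, grid.test_replicate_index)
        tr_mask = prep.metadata["replicate_index"].astype(int) != grid.test_replicate_index
        y_train, classes = dummy_code(labels[tr_mask.to_numpy()])
        y_test = _encode_like(labels[~tr_mask.to_numpy()], classes)
        base = fit_pls_raw(train.intensities, y_train, cand.n_components,
                           scaling=cand.scaling, class_labels=classes)
        vip = vip_scores(base)
        for cutoff in grid.vip_cutoffs:
            sel = select_by_vip(vip, cutoff)
            if sel.retained_count == 0:
                out.append(ModelCandidate(
                    cand.normalization, cand.scaling, cand.n_components,
                    "vip_sweep", vip_cutoff=cutoff, retained_variable_count=0,
                    feasible=False, reason="no variables above VIP cutoff"))
                continue
            mask = sel.retained_mask
            Xtr = train.intensities[:, mask]
            Xte = test.intensities[:, mask]
            A = min(cand.n_components, Xtr.shape[1])
            try:
                model = fit_pls_raw(Xtr, y_train, A, scaling=cand.scaling,
                                    variable_ids=train.wavenumbers[mask],
                                    class_labels=classes)
                q2 = q2y(Xtr, y_train, A, n_folds=grid.n_folds,
                         scaling=cand.scaling)
                perm = permutation_test(
                    Xtr, y_train, A, n_permutations=grid.n_permutations,
                    seed=_cell_seed(grid.seed, cand.normalization,
                                    cand.scaling, A, extra=int(cutoff * 10) + 1),
                    scaling=cand.scaling, n_folds=grid.n_folds)
            except (FitError, ValueError) as exc:
                out.append(ModelCandidate(
                    cand.normalization, cand.scaling, cand.n_components,
                    "vip_sweep", vip_cutoff=cutoff,
                    retained_variable_count=int(mask.sum()),
                    feasible=False, reason=str(exc)))
                continue
            model.q2y_cum = q2
            out.append(ModelCandidate(
                cand.normalization, cand.scaling, A, "vip_sweep",
                vip_cutoff=cutoff, retained_variable_count=int(mask.sum()),
                r2y=model.r2y_cum, q2y=q2,
                rmsee=rmsee(model, Xtr, y_train),
                rmsep=rmsep(model, Xte, y_test),
                r2y_intercept=perm.r2y_intercept,
                q2y_intercept=perm.q2y_intercept,
                valid=perm.valid, model=model,
                selected_wavenumbers=train.wavenumbers[mask]))
    return out


def _encode_like(labels: np.ndarray, classes: list) -> np.ndarray:
    if len(classes) == 2:
        return (labels == classes[1]).astype(float)[:, None]
    return np.array([[1.0 if lab == c else 0.0 for c in classes] for lab in labels])


class NoWinnerError(RuntimeError):
    """No valid candidate survived the permutation gate."""


def select_best(candidates: list[ModelCandidate]) -> ModelCandidate | None:
    """Lowest-RMSEP valid candidate; ties broken by higher Q2Y, fewer
    retained variables, then fewer components.  Returns None when no
    candidate is valid (the caller keeps the full table)."""
    if not candidates:
        raise ValueError("no candidates to select from")
    valid = [c for c in candidates
             if c.feasible and c.valid and c.rmsep is not None]
    if not valid:
        return None
    return min(valid, key=lambda c: (c.rmsep, -(c.q2y or 0),
                                     c.retained_variable_count or 0,
                                     c.n_components))


@dataclass
class DiscriminationReport:
    task: str
    group: str | None
    screen_candidates: list
    sweep_candidates: list
    winner: ModelCandidate | None
    winner_months: float | None
    test_accuracy: float | None

    def table(self) -> pd.DataFrame:
        rows = [c.row() for c in self.screen_candidates + self.sweep_candidates]
        return pd.DataFrame(rows)


def run_discrimination(s: SpectrumSet, task: str, grid: GridSpec,
                       group: str | None = None) -> DiscriminationReport:
    """End-to-end selection for one discrimination task.

    ``task='age_within_part'`` discriminates age classes within the plant
    part ``group`` (e.g. ``'tap_root'``); ``task='part_within_age'``
    discriminates the three parts within one age class (``group`` e.g.
    ``'5yr'``).  Runs screening, the VIP sweep, and final selection, and
    reports test-replicate accuracy plus the months conversion for
    two-class age tasks.
    """
    if task == "age_within_part":
        filter_field, label_field = "part", "age_class"
    elif task == "part_within_age":
        filter_field, label_field = "age_class", "part"
    else:
        raise ValueError(f"unknown task {task!r}")
    sub = s
    if group is not None:
        mask = (s.metadata[filter_field] == group).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"no samples with {filter_field}={group!r}")
        sub = s.select_samples(mask)
    labels = _labels_for(sub, label_field)
    if len(set(labels.tolist())) < 2:
        raise ValueError(f"task {task!r} has a single class after filtering")

    preprocessed = preprocess_all(sub, grid.normalizations)
    screen = screen_configurations(sub, labels, grid, preprocessed)
    winners = pick_screen_winners(screen)
    sweep = vip_sweep(sub, labels, winners, grid, preprocessed)
    best = select_best(sweep)

    months = accuracy = None
    if best is not None:
        two_class_age = (label_field == "age_class"
                         and len(set(labels.tolist())) == 2)
        if two_class_age:
            months = rmse_to_months(best.rmsep)
        prep = preprocessed[best.normalization]
        _, test = split_replicates(prep, grid.test_replicate_index)
        te_mask = (prep.metadata["replicate_index"].astype(int)
                   == grid.test_replicate_index).to_numpy()
        true_labels = labels[te_mask]
        mask = np.isin(prep.wavenumbers, best.selected_wavenumbers)
        calls = best.model.classify(test.intensities[:, mask])
        accuracy = float(np.mean(np.asarray(calls) == true_labels))
    return DiscriminationReport(task, group, screen, sweep, best, months, accuracy)
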