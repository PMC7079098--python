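"""High-level Model/Results interface over the registration pipeline.

The library modules expose the individual primitives (phantoms, transforms,
the network, metrics).  This module ties them into the two-object pattern
familiar from statistical packages: a :class:`ContourPropagationModel` holds
the data and every hyperparameter, ``fit(seed)`` runs the progressive
training loop, and the returned :class:`ContourPropagationResults` carries
the trained network state plus all post-estimation tools — propagation,
per-case evaluation, the axial-shift robustness experiment, checkpointing,
and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np

from propnet.errors import ConfigError, InputError, SplitError
from propnet.evaluation import (
    EvalReport,
    ShiftExperimentResult,
    crossval_splits,
    default_grid_spec,
    evaluate_case,
    preprocess_case,
    shift_experiment,
    summarize,
)
from propnet.network import (
    LossWeights,
    ModelState,
    OptimizerSettings,
    ProgressiveSchedule,
    UNetConfig,
    propagate,
)
from propnet.phantom import PatientRecord, make_training_sample
from propnet.transforms import DisplacementField
from propnet.volume import NetworkGridSpec, Volume3D, resample_to_network_grid


def _as_loss_weights(loss: Union[str, LossWeights]) -> LossWeights:
    if isinstance(loss, LossWeights):
        return loss
    return LossWeights.from_preset(loss)


@dataclass
class ContourPropagationModel:
    """A contour-propagation study: data plus every training hyperparameter.

    ``patients`` supplies the training anatomy; each patient contributes its
    pretreatment scan and all fraction scans to the training stream, from
    which supervised registration problems are manufactured on the fly.
    ``fit`` is deterministic given its seed.
    """

    patients: Sequence[PatientRecord]
    network: UNetConfig = dc_field(default_factory=UNetConfig)
    schedule: ProgressiveSchedule = dc_field(default_factory=ProgressiveSchedule)
    loss: Union[str, LossWeights] = "hybrid"
    optimizer: OptimizerSettings = dc_field(default_factory=OptimizerSettings)
    iterations: Optional[int] = None      # default: the full schedule length
    grid_spec: Optional[NetworkGridSpec] = None

    def __post_init__(self):
        self.loss_weights = _as_loss_weights(self.loss)
        if self.grid_spec is None:
            self.grid_spec = default_grid_spec(self.network.input_size)
        if tuple(self.grid_spec.size) != tuple(self.network.input_size):
            raise ConfigError("grid_spec size must match the network input size")
        if self.iterations is None:
            self.iterations = self.schedule.total_length(self.network.levels)
        if self.iterations < 0:
            raise ConfigError("iterations must be >= 0")

    # -- training data ------------------------------------------------------

    def _training_volumes(self) -> list[tuple[Volume3D, Volume3D]]:
        """All (image, mask) pairs, resampled onto the network grid."""
        vols = []
        for p in self.patients:
            for img, msk in [p.pretreatment, *p.fractions]:
                i = resample_to_network_grid(img, self.grid_spec)
                i = i.copy_with(np.clip(i.data, 0.0, 1.0))
                m = resample_to_network_grid(msk, self.grid_spec)
                vols.append((i, m))
        return vols

    def _stream(self, seed: int):
        """Training-sample stream; iteration ``i`` depends only on (seed, i).

        Seeding each draw as ``default_rng([seed, i, ...])`` makes the stream
        independent of how many samples were consumed before — training is
        reproducible even across checkpoint/restart boundaries.
        """
        vols = self._training_volumes()
        amp = self.network.input_size[0] / 128.0
        i = 0
        while True:
            pick = int(np.random.default_rng([seed, i, 0]).integers(len(vols)))
            img, msk = vols[pick]
            yield make_training_sample(
                img, msk, np.random.default_rng([seed, i, 1]),
                amplitude_scale=amp,
            )
            i += 1

    # -- estimation ---------------------------------------------------------

    def fit(self, seed: int = 0) -> "ContourPropagationResults":
        """Train the network with the progressive schedule; deterministic in
        ``seed``.  Raises :class:`TrainingDivergenceError` (carrying the last
        finite state) if the loss becomes non-finite."""
        from propnet.network import train

        if len(self.patients) < 1:
            raise InputError("at least one training patient is required")
        state = ModelState.initialize(
            self.network, np.random.default_rng([seed, 0]))
        state = train(state, self._stream(seed), self.schedule,
                      self.loss_weights, self.optimizer,
                      iterations=self.iterations)
        return ContourPropagationResults(model=self, state=state, seed=seed)

    def results_from_state(self, state: ModelState) -> "ContourPropagationResults":
        """Wrap a previously trained / loaded network state."""
        if tuple(state.config.input_size) != tuple(self.network.input_size):
            raise ConfigError("checkpoint grid does not match the model grid")
        return ContourPropagationResults(model=self, state=state, seed=None)


@dataclass
class ContourPropagationResults:
    """A fitted contour-propagation network plus post-estimation tools."""

    model: ContourPropagationModel
    state: ModelState
    seed: Optional[int] = None

    # -- core use -----------------------------------------------------------

    def propagate(self, pre_image: Volume3D, pre_mask: Volume3D,
                  fraction_image: Volume3D,
                  pre_shift_mm: float = 0.0) -> tuple[Volume3D, DisplacementField]:
        """Propagate a pretreatment contour onto a fraction image.

        Inputs may be on any grid covering the network window; they are
        resampled onto the network grid first.  Returns the binary mask on
        that grid and the predicted displacement field (voxel units).
        """
        pi, pm, fi = preprocess_case(pre_image, pre_mask, fraction_image,
                                     self.model.grid_spec,
                                     pre_shift_mm=pre_shift_mm)
        return propagate(self.state, pi, pm, fi)

    def evaluate(self, patients: Union[PatientRecord, Sequence[PatientRecord]],
                 method: str = "network") -> list[EvalReport]:
        """Per-(patient, fraction) metric reports for the fitted network."""
        if isinstance(patients, PatientRecord):
            patients = [patients]
        reports = []
        for p in patients:
            pre_img, pre_mask = p.pretreatment
            for k, (f_img, f_mask) in enumerate(p.fractions):
                mask, fld = self.propagate(pre_img, pre_mask, f_img)
                truth = resample_to_network_grid(f_mask, self.model.grid_spec)
                reports.append(
                    evaluate_case(mask, truth, fld, patient_id=p.patient_id,
                                  fraction=k, method=method)
                )
        return reports

    def baseline_reports(self, patients: Union[PatientRecord, Sequence[PatientRecord]]
                         ) -> list[EvalReport]:
        """No-registration baseline: the pretreatment contour taken as-is."""
        if isinstance(patients, PatientRecord):
            patients = [patients]
        reports = []
        for p in patients:
            pm = resample_to_network_grid(p.pretreatment[1], self.model.grid_spec)
            for k, (_, f_mask) in enumerate(p.fractions):
                truth = resample_to_network_grid(f_mask, self.model.grid_spec)
                reports.append(
                    evaluate_case(pm, truth, None, patient_id=p.patient_id,
                                  fraction=k, method="no-registration")
                )
        return reports

    def shift_experiment(self, patient: PatientRecord,
                         shifts_mm: Sequence[float] = tuple(range(-5, 6)),
                         ) -> ShiftExperimentResult:
        """Axial-shift robustness sweep for one patient (see
        :func:`propnet.evaluation.shift_experiment`)."""
        return shift_experiment(self.state, patient, shifts_mm,
                                grid_spec=self.model.grid_spec)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        self.state.save(path)

    @classmethod
    def load(cls, path, model: ContourPropagationModel) -> "ContourPropagationResults":
        return model.results_from_state(ModelState.load(path))

    # -- reporting ----------------------------------------------------------

    @property
    def loss_log(self) -> np.ndarray:
        """(iteration, total, overlap, deformation) rows as an array."""
        return np.asarray(self.state.loss_log, dtype=np.float64).reshape(-1, 4)

    def summary(self, patients: Optional[Sequence[PatientRecord]] = None) -> str:
        """Plain-text summary of the fit (and optionally held-out metrics)."""
        m, cfg = self.model, self.state.config
        lines = [
            "Contour Propagation Results",
            "=" * 54,
            f"{'grid':<28}{cfg.input_size}",
            f"{'resolution levels':<28}{cfg.levels}",
            f"{'base features':<28}{cfg.base_features}",
            f"{'loss weights (overlap,dvf)':<28}"
            f"({m.loss_weights.k_overlap:g}, {m.loss_weights.k_dvf:g})",
            f"{'iterations':<28}{self.state.iteration}",
            f"{'optimizer':<28}SGD lr={m.optimizer.learning_rate:g} "
            f"momentum={m.optimizer.momentum:g}",
            f"{'training patients':<28}{len(m.patients)}",
            f"{'seed':<28}{self.seed}",
        ]
        log = self.loss_log
        if log.size:
            n = min(50, len(log))
            lines += [
                f"{'loss (first %d mean)' % n:<28}{log[:n, 1].mean():.4f}",
                f"{'loss (last %d mean)' % n:<28}{log[-n:, 1].mean():.4f}",
            ]
        if patients is not None:
            pooled = summarize(self.evaluate(patients))
            lines.append("-" * 54)
            lines.append("held-out metrics (mean +/- sd)")
            units = {"dice": "", "hd95": " mm", "centroid_distance": " mm",
                     "folding_fov": " %", "folding_prostate": " %"}
            for key, s in pooled.items():
                lines.append(
                    f"{key:<28}{s['mean']:.4f} +/- {s['sd']:.4f}{units.get(key, '')}"
                    f"  (n={s['n']})"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cross-validation over patients
# ---------------------------------------------------------------------------

def cross_validate(patients: Sequence[PatientRecord], seed: int = 0,
                   **model_kwargs) -> dict:
    """Rotating train/validation/test cross-validation.

    Each fold trains a fresh model (identical hyperparameters, per-fold seed
    derived from ``seed``) on the fold's training patients and evaluates on
    its test patient; with five patients this is the 3/1/1 rotation in which
    every patient appears once in test and once in validation.  The
    validation patient is held out of training; its reports are returned for
    monitoring but never pooled into the test summary.
    """
    if len(patients) < 3:
        raise SplitError("cross-validation needs >= 3 patients")
    folds = crossval_splits(len(patients))
    fold_out = []
    for i, fold in enumerate(folds):
        model = ContourPropagationModel(
            patients=[patients[j] for j in fold["train"]], **model_kwargs)
        res = model.fit(seed=int(np.random.default_rng([seed, i]).integers(2**31)))
        test_reports = res.evaluate(patients[fold["test"]])
        val_reports = res.evaluate(patients[fold["validation"]])
        fold_out.append({
            "fold": i, "split": fold,
            "test_reports": test_reports,
            "validation_reports": val_reports,
        })
    pooled = summarize([r for f in fold_out for r in f["test_reports"]])
    return {"folds": fold_out, "summary": pooled}
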