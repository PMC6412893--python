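"""End-to-end orchestration: windows -> scaling -> per-sensor SDAE features
-> Boosting K-Fold boosted trees -> evaluation + separability report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import boost_kfold as bk
from . import io_preprocess as iop
from . import metrics as mx
from . import sdae
from .separability import DivergenceReport, divergence_report

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "DATASET_SDAE_PRESETS",
    "run_pipeline",
]

#: per-dataset SDAE shapes used in the published evaluation: encoder widths,
#: corruption rate, batch size and epoch budget for each sensor stack
DATASET_SDAE_PRESETS: dict[str, dict] = {
    "HMMwithPre": {
        "default": dict(n_hidden=(400, 200, 40), dropout=0.4, batch_size=32, epochs=20),
        "pressure": dict(n_hidden=(150, 70, 20), dropout=0.4, batch_size=32, epochs=20),
    },
    "HMMwithoutPre": {
        "default": dict(n_hidden=(400, 200, 30), dropout=0.4, batch_size=32, epochs=4),
    },
    "HSBD": {
        "default": dict(n_hidden=(100, 30), dropout=0.4, batch_size=32, epochs=2),
    },
    "HDBD": {
        "default": dict(n_hidden=(30,), dropout=0.4, batch_size=32, epochs=20),
    },
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the full pipeline on raw recordings."""

    window: iop.WindowConfig = field(default_factory=lambda: iop.WindowConfig(128, 128))
    sdae: Mapping[str, sdae.SDAEConfig] | sdae.SDAEConfig = field(
        default_factory=lambda: sdae.SDAEConfig(n_hidden=(100, 30), epochs=15)
    )
    k: int = 5
    test_fraction: float = 0.3
    gbdt: bk.GBDTParams = field(default_factory=bk.GBDTParams)
    fine_tune: bool = True
    seed: int = 0

    def sdae_for(self, sensor: str) -> sdae.SDAEConfig:
        if isinstance(self.sdae, sdae.SDAEConfig):
            return self.sdae
        return self.sdae.get(sensor, self.sdae["default"])


@dataclass
class PipelineResult:
    report: mx.EvalReport
    divergence: DivergenceReport
    model: bk.BoostKFoldModel
    stacks: dict[str, sdae.EncoderStack]
    scaler: iop.ScalerParams
    train_features: sdae.FeatureMatrix
    test_features: sdae.FeatureMatrix


def run_pipeline(
    recordings: Sequence[iop.RawRecording],
    schema: Sequence[iop.SensorSpec],
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run preprocessing, feature learning, classification and diagnostics.

    Recordings are windowed per recording and pooled; a stratified 70/30
    split is scaled with training extrema; one SDAE stack per sensor is
    pretrained greedily and fine-tuned on the training windows; learned
    features are concatenated and classified with Boosting K-Fold majority
    voting.  The returned report evaluates the held-out windows and the
    divergence report compares their raw vs. learned feature scatter.
    """
    cfg = cfg or PipelineConfig()
    samples = iop.windows_to_samples(recordings, cfg.window, schema)
    train, test = iop.split_train_test(samples, cfg.test_fraction, seed=cfg.seed)
    scaler = iop.fit_minmax(train)
    train_s = iop.apply_minmax(train, scaler)
    test_s = iop.apply_minmax(test, scaler)

    stacks: dict[str, sdae.EncoderStack] = {}
    train_feats: dict[str, object] = {}
    test_feats: dict[str, object] = {}
    for spec in schema:
        scfg = cfg.sdae_for(spec.name)
        stack = sdae.build_stack(train_s.data[spec.name], scfg)
        if cfg.fine_tune:
            stack = sdae.fine_tune_stack(stack, train_s.data[spec.name], scfg)
        stacks[spec.name] = stack
        train_feats[spec.name] = sdae.extract_features(stack, train_s.data[spec.name])
        test_feats[spec.name] = sdae.extract_features(stack, test_s.data[spec.name])
    ftrain = sdae.concat_sensor_features(train_feats, labels=train_s.labels)
    ftest = sdae.concat_sensor_features(test_feats, labels=test_s.labels)

    plan = bk.stratified_folds(ftrain.labels, k=cfg.k, seed=cfg.seed)
    model = bk.train_boosting_kfold(ftrain.features, ftrain.labels, plan, params=cfg.gbdt)
    y_pred = bk.predict_majority_vote(model, ftest.features)
    report = mx.evaluate(ftest.labels, y_pred)

    div = divergence_report(test_s.stacked(), ftest.features, ftest.labels)
    return PipelineResult(
        report=report,
        divergence=div,
        model=model,
        stacks=stacks,
        scaler=scaler,
        train_features=ftrain,
        test_features=ftest,
    )
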