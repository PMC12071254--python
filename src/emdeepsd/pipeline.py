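"""End-to-end pipelines: decompose -> stack -> meta-network.

``train_pipeline`` fits either the SSA variant (EM-DeepSSA: three SSA
subsequences x five learners = 15 meta-features, 20 LSTM units) or the
EMD variant (EM-DeepEMD: two subsequences x five learners = 10
meta-features, 10 LSTM units) on a labelled profile matrix and returns a
sealed :class:`ModelBundle`. ``predict_pipeline`` replays the identical
preprocessing (same decomposition parameters, learner manifest and
normalisation statistics) on new profiles. ``score_pipeline`` computes
the benchmark diversity/deconvolution score table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
import joblib
import numpy as np
import pandas as pd

from . import __version__
from .decomposition import (
    DEFAULT_PE_THRESHOLD,
    DEFAULT_SSA_GROUPING,
    DEFAULT_SSA_WINDOW,
    emd_decompose,
    ssa_decompose,
)
from .diversity import (
    FounderMatrix,
    deconvolve,
    diversity_scores,
)
from .learners import (
    FittedStack,
    LearnerSpec,
    MetaFeatureMatrix,
    build_meta_features_train,
    predict_meta,
)
from .motifs import ProfileMatrix
from .network import NetworkConfig, TrainedNetwork, train_network


@dataclass
class PipelineConfig:
    """Everything that parameterises a training run."""

    variant: str = "ssa"  # "ssa" or "emd"
    ssa_window: int = DEFAULT_SSA_WINDOW
    pe_threshold: float = DEFAULT_PE_THRESHOLD
    folds: int = 10
    seed: int = 0
    fast_grids: bool = False
    use_attention: bool = True
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 0.001
    lstm_layers: int = 2
    hidden_units: int | None = None  # default 20 for SSA, 10 for EMD

    def __post_init__(self) -> None:
        if self.variant not in ("ssa", "emd"):
            raise ValueError("variant must be 'ssa' or 'emd'")
        if self.hidden_units is None:
            self.hidden_units = 20 if self.variant == "ssa" else 10


def decompose_matrix(
    pm: ProfileMatrix, variant: str, ssa_window: int = DEFAULT_SSA_WINDOW,
    pe_threshold: float = DEFAULT_PE_THRESHOLD,
) -> dict[str, np.ndarray]:
    """Per-sample decomposition into named subsequence matrices.

    SSA yields {"SSA1", "SSA2", "SSA3"}; EMD yields {"EMD1", "EMD2"}
    (high-PE and low-PE pools). Each value is an n_samples x 256 matrix.
    """
    n = pm.n_samples
    if variant == "ssa":
        names = ["SSA1", "SSA2", "SSA3"]
        out = {name: np.empty((n, 256)) for name in names}
        for i in range(n):
            dec = ssa_decompose(pm.values[i], L=ssa_window,
                                grouping=_ssa_grouping(ssa_window))
            for name, series in zip(names, dec.subsequences):
                out[name][i] = series
        return out
    if variant == "emd":
        out = {"EMD1": np.empty((n, 256)), "EMD2": np.empty((n, 256))}
        for i in range(n):
            dec = emd_decompose(pm.values[i], pe_threshold=pe_threshold)
            out["EMD1"][i], out["EMD2"][i] = dec.subsequences
        return out
    raise ValueError(f"unknown variant {variant!r}")


def _ssa_grouping(window: int) -> tuple[tuple[int, ...], ...]:
    if window == DEFAULT_SSA_WINDOW:
        return DEFAULT_SSA_GROUPING
    # same three-group scheme generalised: 1st, 2nd-3rd, rest
    return ((1,), (2, 3), tuple(range(4, window + 1)))


@dataclass
class ModelBundle:
    """A trained pipeline: decomposition parameters, base-learner stack,
    meta-network, and the training meta-features for audit."""

    config: PipelineConfig
    stack: FittedStack
    net: TrainedNetwork
    train_meta: MetaFeatureMatrix
    train_probabilities: np.ndarray
    version: str = __version__

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": self.version,
            "variant": self.config.variant,
            "ssa_window": self.config.ssa_window,
            "pe_threshold": self.config.pe_threshold,
            "seed": self.config.seed,
            "columns": self.stack.columns,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(self, path / "bundle.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        bundle: ModelBundle = joblib.load(path / "bundle.joblib")
        if manifest.get("version") != __version__:
            warnings.warn(
                f"bundle was written by version {manifest.get('version')}, "
                f"running {__version__}", stacklevel=2,
            )
        return bundle


def train_pipeline(
    pm: ProfileMatrix,
    variant: str = "ssa",
    config: PipelineConfig | None = None,
    specs: list[LearnerSpec] | None = None,
) -> ModelBundle:
    """Fit the full classifier on a labelled profile matrix."""
    if pm.labels is None:
        raise ValueError("training requires labels")
    cfg = config or PipelineConfig(variant=variant)
    if config is not None and config.variant != variant:
        raise ValueError("variant argument disagrees with config.variant")
    counts = np.bincount(pm.labels, minlength=2)
    if counts.min() < cfg.folds:
        raise ValueError(
            f"need >= {cfg.folds} samples per class for {cfg.folds}-fold CV"
        )
    try:
        subsequences = decompose_matrix(
            pm, cfg.variant, ssa_window=cfg.ssa_window,
            pe_threshold=cfg.pe_threshold,
        )
    except Exception as exc:
        raise RuntimeError(f"decomposition stage failed: {exc}") from exc
    try:
        meta, stack = build_meta_features_train(
            subsequences, pm.labels, pm.sample_ids, specs=specs,
            folds=cfg.folds, seed=cfg.seed, fast=cfg.fast_grids,
        )
    except Exception as exc:
        raise RuntimeError(f"base-learner stage failed: {exc}") from exc
    net_cfg = NetworkConfig(
        lstm_layers=cfg.lstm_layers,
        hidden_units=cfg.hidden_units,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
        use_attention=cfg.use_attention,
    )
    try:
        net = train_network(meta.values, pm.labels, net_cfg, columns=meta.columns)
    except Exception as exc:
        raise RuntimeError(f"meta-network stage failed: {exc}") from exc
    # stored training probabilities follow the prediction path (full-data
    # refits), so a reloaded bundle reproduces them exactly
    pred_meta = predict_meta(stack, subsequences, pm.sample_ids)
    train_probs = net.predict(pred_meta.values, columns=pred_meta.columns)
    return ModelBundle(
        config=cfg, stack=stack, net=net, train_meta=meta,
        train_probabilities=train_probs,
    )


def predict_pipeline(bundle: ModelBundle, pm: ProfileMatrix) -> pd.DataFrame:
    """Cancer probabilities for new profiles through a trained bundle."""
    cfg = bundle.config
    subsequences = decompose_matrix(
        pm, cfg.variant, ssa_window=cfg.ssa_window,
        pe_threshold=cfg.pe_threshold,
    )
    meta = predict_meta(bundle.stack, subsequences, pm.sample_ids)
    probs = bundle.net.predict(meta.values, columns=meta.columns)
    out = pd.DataFrame({"probability": probs}, index=pm.sample_ids)
    out.index.name = "sample_id"
    if pm.labels is not None:
        out["label"] = pm.labels
    return out


SCORE_COLUMNS = (
    ["MDS"]
    + [f"MDS_Sub-{s}" for s in ("SSA1", "SSA2", "SSA3", "EMD1", "EMD2")]
    + ["MDS-SSA", "MDS-EMD"]
    + [f"F-profile_{i}" for i in range(1, 7)]
)


def score_pipeline(
    pm: ProfileMatrix,
    founders: FounderMatrix,
    ssa_window: int = DEFAULT_SSA_WINDOW,
) -> pd.DataFrame:
    """Benchmark score table: MDS, the seven decomposition diversity
    scores, and six founder-profile contributions per sample."""
    rows = []
    for i in range(pm.n_samples):
        profile = pm.values[i]
        ssa = ssa_decompose(profile, L=ssa_window,
                            grouping=_ssa_grouping(ssa_window))
        emd = emd_decompose(profile)
        ds = diversity_scores(profile, ssa, emd)
        contrib = deconvolve(profile, founders)
        rows.append(
            [ds.mds]
            + [ds.mds_sub[s] for s in ("SSA1", "SSA2", "SSA3", "EMD1", "EMD2")]
            + [ds.mds_ssa, ds.mds_emd]
            + list(contrib.p)
        )
    df = pd.DataFrame(rows, index=pm.sample_ids, columns=SCORE_COLUMNS)
    df.index.name = "sample_id"
    return df
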