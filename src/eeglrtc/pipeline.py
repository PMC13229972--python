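"""End-to-end orchestration: ingest -> features -> embed -> DFA -> bootstrap.

A RunConfig captures every tunable of the pipeline and is echoed verbatim
into each report so a run can be reproduced from its own output. Recordings
come from EDF files (header sampling rate and labels honored) or delimited
numeric matrices (channels x samples, sampling rate supplied by the caller).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dfa import DFAResult, mean_based_dfa, norm_based_dfa
from .embedding import (
    Embedding,
    elbow_dimension,
    explained_variance,
    geodesic_distances,
    isomap_embed,
    knn_adjacency,
    pairwise_euclidean,
    pca_embed,
    select_k,
    classical_mds,
    trustworthiness,
)
from .preprocess import (
    ALPHA_BAND,
    FeatureMatrix,
    Recording,
    bandpass_alpha,
    build_feature_matrix,
    zscore_channels,
)
from .stats import moving_block_bootstrap_alpha

__all__ = [
    "RunConfig",
    "read_recording",
    "write_matrix",
    "read_matrix",
    "run_pipeline",
    "k_sensitivity_sweep",
]

log = logging.getLogger("eeglrtc")


@dataclass
class RunConfig:
    """All pipeline tunables; serialized into every report."""

    input_path: str = ""
    fs: float | None = None  # required for delimited input, else from EDF header
    band: tuple[float, float] = ALPHA_BAND
    window_length_s: float = 2.0
    method: str = "isomap"  # isomap | pca
    dim: int | str = "auto"  # elbow rule when "auto"
    k: int | str = "auto"  # smallest connectivity-preserving k when "auto"
    approach: str = "mean"  # mean | norm
    detrend_order: int = 1
    n_boot: int = 1000
    seed: int = 0
    excluded_channels: list[str] = field(default_factory=list)
    bonferroni_factor: int = 4
    trust_k: list[int] = field(default_factory=lambda: [5, 7])
    default_dim: int = 3  # fallback when the elbow is unclear

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value (YAML) config file; kwargs override keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d


def read_recording(
    path: str | Path,
    fs: float | None = None,
    delimiter: str = ",",
) -> Recording:
    """Read an EDF file or a delimited channels-x-samples matrix.

    For EDF the header sampling rate and channel labels are used unless
    `fs` overrides the header. Delimited matrices require `fs`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data(),
            fs=fs if fs is not None else float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            subject_id=path.stem,
        )
    if fs is None:
        raise ValueError("fs must be given for delimited matrix input")
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed delimited matrix in {path}: {exc}") from exc
    return Recording(data=data, fs=fs, subject_id=path.stem)


def write_matrix(
    values: np.ndarray, path: str | Path, columns: list[str] | None = None
) -> None:
    """Write a matrix as comma-separated text (header row when labeled)."""
    df = pd.DataFrame(np.asarray(values))
    if columns is not None:
        df.columns = columns
    df.to_csv(path, index=False, header=columns is not None)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a matrix written by `write_matrix` (header row auto-detected)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    first = path.open().readline()
    has_header = any(
        not _is_number(tok) for tok in first.strip().split(",") if tok != ""
    )
    df = pd.read_csv(path, header=0 if has_header else None)
    return df.to_numpy(dtype=float)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _embed_features(X: FeatureMatrix, config: RunConfig) -> tuple[Embedding, dict]:
    """Embed the feature matrix per config; returns embedding + diagnostics."""
    if config.method == "isomap":
        D = pairwise_euclidean(X)
        k = select_k(D) if config.k == "auto" else int(config.k)
        G = geodesic_distances(knn_adjacency(D, k))
        full = classical_mds(G, d=1)  # full spectrum for the elbow
        spectrum = full.eigenvalues
    elif config.method == "pca":
        k = None
        spectrum = pca_embed(X, d=1).eigenvalues
    else:
        raise ValueError(f"unknown method {config.method!r}")

    if config.dim == "auto":
        elbow = elbow_dimension(spectrum, default=config.default_dim)
        d = elbow.dimension
        elbow_clear = elbow.clear
    else:
        d = int(config.dim)
        elbow_clear = None

    if config.method == "isomap":
        emb = isomap_embed(X, d=d, k=k)
    else:
        emb = pca_embed(X, d=d)

    diag = {
        "k_used": k,
        "d": d,
        "elbow_clear": elbow_clear,
        "explained_variance_pct": explained_variance(spectrum, d),
        "trustworthiness": {
            str(kt): trustworthiness(X, emb, n_neighbors=kt) for kt in config.trust_k
        },
        "eigenvalues": spectrum.tolist(),
    }
    return emb, diag


def _run_dfa(emb: Embedding, config: RunConfig) -> DFAResult:
    run = mean_based_dfa if config.approach == "mean" else norm_based_dfa
    return run(emb, order=config.detrend_order)


def run_pipeline(
    config: RunConfig, recording: Recording | None = None
) -> dict:
    """Execute the full pipeline and return a JSON-serializable report.

    Stages: read -> z-score -> band-pass -> band-power features -> embedding
    (with k selection and elbow dimensionality) -> DFA -> moving-block
    bootstrap. With a fixed seed the report is deterministic apart from its
    timestamp.
    """
    try:
        if recording is None:
            log.info("stage=read input=%s", config.input_path)
            recording = read_recording(config.input_path, fs=config.fs)
        if config.excluded_channels:
            recording = recording.drop_channels(config.excluded_channels)
        log.info("stage=zscore channels=%d", recording.n_channels)
        rec = zscore_channels(recording)
        log.info("stage=bandpass band=%s", (config.band,))
        rec = bandpass_alpha(rec, *config.band)
        log.info("stage=features window_s=%s", config.window_length_s)
        X = build_feature_matrix(rec, config.window_length_s, config.band)
        log.info("stage=embedding method=%s", config.method)
        emb, diag = _embed_features(X, config)
        log.info("stage=dfa approach=%s", config.approach)
        res = _run_dfa(emb, config)
        boot = None
        if config.n_boot > 0:
            log.info("stage=bootstrap n=%d", config.n_boot)
            boot = moving_block_bootstrap_alpha(
                emb,
                approach=config.approach,
                n_resamples=config.n_boot,
                seed=config.seed,
                order=config.detrend_order,
            )
    except Exception as exc:
        raise type(exc)(f"[pipeline] {exc}") from exc

    report = {
        "software": {"name": "eeglrtc", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "n_windows": X.n_windows,
        "n_channels": X.n_channels,
        "embedding": {k: v for k, v in diag.items() if k != "eigenvalues"},
        "eigenvalues": diag["eigenvalues"],
        "dfa": {
            "alpha": res.alpha,
            "r_squared": res.r_squared,
            "approach": res.approach,
            "detrend_order": res.detrend_order,
            "scales": res.scales.tolist(),
            "fluctuations": res.fluctuations.tolist(),
            "per_dimension_alphas": (
                None
                if res.per_dimension_alphas is None
                else res.per_dimension_alphas.tolist()
            ),
            "short_series": res.short_series,
        },
    }
    if boot is not None:
        report["bootstrap"] = {
            "alpha_mean": boot.alpha_mean,
            "ci_low": boot.ci_low,
            "ci_high": boot.ci_high,
            "n_resamples": boot.n_resamples,
            "block_length": boot.block_length,
            "seed": boot.seed,
        }
    return report


def k_sensitivity_sweep(
    X: FeatureMatrix | np.ndarray, config: RunConfig
) -> pd.DataFrame:
    """Rerun embedding + DFA for k in {k*-2, ..., k*+2}.

    k* is the adaptively selected (or configured) neighborhood size. Values
    below 1 are clipped with a warning; a k whose graph is disconnected is
    reported with NaN alpha and connected=False rather than aborting the
    sweep. The returned frame carries the max |alpha - alpha(k*)| deviation
    in ``DataFrame.attrs["max_alpha_deviation"]``.
    """
    D = pairwise_euclidean(X)
    n = D.shape[0]
    k_star = select_k(D) if config.k == "auto" else int(config.k)
    lo = k_star - 2
    if lo < 1:
        log.warning("k sweep clipped at k=1 (k*=%d)", k_star)
        lo = 1
    ks = [k for k in range(lo, k_star + 3) if k <= n - 1]

    if config.dim == "auto":
        G = geodesic_distances(knn_adjacency(D, k_star))
        d = elbow_dimension(
            classical_mds(G, 1).eigenvalues, default=config.default_dim
        ).dimension
    else:
        d = int(config.dim)

    rows = []
    for k in ks:
        graph = knn_adjacency(D, k)
        if not graph.is_connected():
            rows.append(
                {"k": k, "alpha": np.nan, "r_squared": np.nan, "connected": False}
            )
            continue
        emb = isomap_embed(X, d=d, k=k)
        res = _run_dfa(emb, config)
        rows.append(
            {"k": k, "alpha": res.alpha, "r_squared": res.r_squared, "connected": True}
        )
    table = pd.DataFrame(rows)
    table["is_selected"] = table["k"] == k_star
    ref = table.loc[table["is_selected"], "alpha"].iloc[0]
    table.attrs["max_alpha_deviation"] = float(
        (table.loc[table["connected"], "alpha"] - ref).abs().max()
    )
    return table


def save_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
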