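"""Readers and writers for the package's standard on-disk formats.

PSTHs travel as CSV (one row per neuron, header of bin start-times in ms)
or HDF5; rasters, data matrices, pattern sets and movies as HDF5; movies
additionally as multi-page grayscale TIFF; similarity results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .aggregation import SimilarityResult
from .core import BasisPatternSet, DataMatrix
from .neural_data import PSTHSet, TrialRaster
from .stimuli import MovieStimulus


# ---------------------------------------------------------------- PSTH CSV

def write_psth_csv(path, psth: PSTHSet) -> None:
    starts = np.arange(psth.n_bins) * psth.bin_width_ms
    df = pd.DataFrame(psth.rates, columns=[f"{s:g}" for s in starts])
    df.to_csv(path, index=False)


def read_psth_csv(path, bin_width_ms: float | None = None) -> PSTHSet:
    df = pd.read_csv(path)
    starts = np.array([float(c) for c in df.columns])
    if bin_width_ms is None:
        bin_width_ms = float(starts[1] - starts[0]) if starts.size > 1 else 20.0
    return PSTHSet(rates=df.to_numpy(dtype=float), bin_width_ms=bin_width_ms)


# ---------------------------------------------------------------- HDF5

def write_psth_h5(path, psth: PSTHSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("psth")
        g.create_dataset("rates", data=psth.rates)
        g.create_dataset("bin_width_ms", data=psth.bin_width_ms)
        g.create_dataset("centered", data=psth.centered)
        if psth.feature_means is not None:
            g.create_dataset("feature_means", data=psth.feature_means)


def read_psth_h5(path) -> PSTHSet:
    with h5py.File(path, "r") as f:
        g = f["psth"]
        means = g["feature_means"][()] if "feature_means" in g else None
        return PSTHSet(rates=g["rates"][()],
                       bin_width_ms=float(g["bin_width_ms"][()]),
                       centered=bool(g["centered"][()]),
                       feature_means=means)


def write_raster_h5(path, raster: TrialRaster) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("raster")
        g.create_dataset("counts", data=raster.counts)
        g.create_dataset("bin_width_ms", data=raster.bin_width_ms)


def read_raster_h5(path) -> TrialRaster:
    with h5py.File(path, "r") as f:
        g = f["raster"]
        return TrialRaster(counts=g["counts"][()],
                           bin_width_ms=float(g["bin_width_ms"][()]))


def write_matrix_h5(path, matrix: DataMatrix) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("matrix")
        g.create_dataset("values", data=matrix.values)
        g.create_dataset("centered", data=matrix.centered)
        g.attrs["provenance"] = matrix.provenance
        if matrix.feature_means is not None:
            g.create_dataset("feature_means", data=matrix.feature_means)


def read_matrix_h5(path) -> DataMatrix:
    with h5py.File(path, "r") as f:
        g = f["matrix"]
        means = g["feature_means"][()] if "feature_means" in g else None
        return DataMatrix(values=g["values"][()],
                          centered=bool(g["centered"][()]),
                          feature_means=means,
                          provenance=g.attrs.get("provenance", ""))


def write_patterns_h5(path, ps: BasisPatternSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("patterns")
        g.create_dataset("matrix", data=ps.patterns)
        g.create_dataset("variance_fractions", data=ps.variance_fractions)
        g.create_dataset("threshold", data=ps.variance_threshold)
        g.attrs["ambient_dim"] = ps.ambient_dim
        g.attrs["provenance"] = ps.provenance


def read_patterns_h5(path) -> BasisPatternSet:
    with h5py.File(path, "r") as f:
        g = f["patterns"]
        return BasisPatternSet(patterns=g["matrix"][()],
                               variance_fractions=g["variance_fractions"][()],
                               variance_threshold=float(g["threshold"][()]),
                               ambient_dim=int(g.attrs["ambient_dim"]),
                               provenance=g.attrs.get("provenance", ""))


def write_patterns_csv(path, ps: BasisPatternSet) -> None:
    cols = {f"pattern_{i + 1}": ps.patterns[:, i]
            for i in range(ps.patterns.shape[1])}
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------- movies

def write_movie_h5(path, movie: MovieStimulus, **metadata) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("movie")
        g.create_dataset("frames", data=movie.frames.astype(np.float32))
        g.create_dataset("frame_duration_ms", data=movie.frame_duration_ms)
        for k, v in metadata.items():
            g.attrs[k] = v


def read_movie_h5(path) -> MovieStimulus:
    with h5py.File(path, "r") as f:
        g = f["movie"]
        return MovieStimulus(frames=g["frames"][()].astype(float),
                             frame_duration_ms=float(g["frame_duration_ms"][()]))


def write_movie_tiff(path, movie: MovieStimulus) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32),
                     photometric="minisblack",
                     metadata={"frame_duration_ms": movie.frame_duration_ms})


def read_movie_tiff(path, frame_duration_ms: float = 40.0) -> MovieStimulus:
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStimulus(frames=frames, frame_duration_ms=frame_duration_ms)


# ---------------------------------------------------------------- results

def similarity_result_dict(res: SimilarityResult) -> dict:
    c = res.chance
    return {
        "set_sizes": list(res.set_sizes),
        "k_agg": res.k_agg,
        "lower_bound": res.lower_bound,
        "upper_bound": res.upper_bound,
        "rank_threshold": res.rank_threshold,
        "similarity_index": res.s,
        "p_value": res.p_value,
        "chance": {
            "mean": c.mean_chance,
            "sd": float(np.std(c.samples, ddof=1)) if c.samples.size > 1 else 0.0,
            "n_draws": c.n_draws,
            "ambient_dim": int(c.ambient_dim),
            "seed": None if c.seed is None else int(c.seed),
        },
    }


def write_similarity_json(path, res: SimilarityResult, **extra) -> None:
    payload = similarity_result_dict(res)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
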