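"""File round-tripping and run configuration.

Matrices travel as delimited text (CSV with region labels) so outputs are
human-diffable; `.npz` archives are supported as a faster alternative.
Every FC written to disk carries a JSON sidecar recording band, parameters,
seed and package version, and every artifact can be re-read by the
package's own readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .empirical import RegionalRecording
from .forward import BandFC, BandSpec, DEFAULT_BANDS
from .graph import StructuralConnectome
from .params import PARAM_BOUNDS, SGMParams

__all__ = [
    "read_matrix", "write_matrix",
    "save_connectome", "load_connectome",
    "save_band_fc", "load_band_fc",
    "save_recording", "load_recording",
    "RunConfig", "load_config", "config_hash",
]


def write_matrix(path: Union[str, Path], matrix: np.ndarray,
                 labels: Optional[Sequence[str]] = None) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, matrix=matrix)
        return
    n = matrix.shape[0]
    labels = list(labels) if labels is not None else [f"r{i:03d}" for i in range(n)]
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, float_format="%.17g")


def read_matrix(path: Union[str, Path]) -> Tuple[np.ndarray, List[str]]:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            m = archive["matrix"]
        return m, [f"r{i:03d}" for i in range(m.shape[0])]
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.index]


def save_connectome(directory: Union[str, Path], sc: StructuralConnectome) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(directory / "weights.csv", sc.weights, sc.region_ids)
    write_matrix(directory / "distances.csv", sc.distances, sc.region_ids)
    partner = {}
    if sc.homolog_pairs:
        for i, j in sc.homolog_pairs:
            partner[i] = j
            partner[j] = i
    regions = pd.DataFrame({
        "region_id": sc.region_ids,
        "hemisphere": sc.hemisphere,
        "homolog_index": [partner.get(i, -1) for i in range(sc.n_regions)],
    })
    regions.to_csv(directory / "regions.csv", index=False)
    (directory / "meta.json").write_text(json.dumps(
        {"preprocessed": sc.preprocessed, "version": __version__}, indent=2))


def load_connectome(directory: Union[str, Path]) -> StructuralConnectome:
    directory = Path(directory)
    weights, labels = read_matrix(directory / "weights.csv")
    distances, _ = read_matrix(directory / "distances.csv")
    regions = pd.read_csv(directory / "regions.csv")
    pairs = []
    for i, j in enumerate(regions["homolog_index"]):
        if j >= 0 and i < j:
            pairs.append((i, int(j)))
    meta_path = directory / "meta.json"
    preprocessed = False
    if meta_path.exists():
        preprocessed = bool(json.loads(meta_path.read_text()).get("preprocessed", False))
    return StructuralConnectome(
        weights=weights, distances=distances,
        region_ids=tuple(regions["region_id"]),
        hemisphere=tuple(regions["hemisphere"]),
        homolog_pairs=tuple(pairs) or None,
        preprocessed=preprocessed,
    )


def save_band_fc(path: Union[str, Path], fc: BandFC,
                 params: Optional[SGMParams] = None,
                 seed: Optional[int] = None,
                 labels: Optional[Sequence[str]] = None) -> None:
    path = Path(path)
    write_matrix(path, fc.matrix, labels)
    sidecar = {
        "band": None if fc.band is None else {
            "name": fc.band.name, "f_lo": fc.band.f_lo, "f_hi": fc.band.f_hi,
            "n_points": fc.band.n_points,
        },
        "source": fc.source,
        "params": None if params is None else asdict(params),
        "seed": seed,
        "version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_band_fc(path: Union[str, Path]) -> BandFC:
    path = Path(path)
    matrix, _ = read_matrix(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    band, source = None, "empirical"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        source = sidecar.get("source", "empirical")
        if sidecar.get("band"):
            band = BandSpec(**sidecar["band"])
    return BandFC(band=band, matrix=matrix, source=source)


def save_recording(path: Union[str, Path], rec: RegionalRecording) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, data=rec.data, fs=rec.fs,
                            epoch_count=rec.epoch_count)
        return
    pd.DataFrame(rec.data).to_csv(path, index=False, header=False,
                                  float_format="%.17g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"fs": rec.fs, "epoch_count": rec.epoch_count}))


def load_recording(path: Union[str, Path]) -> RegionalRecording:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            return RegionalRecording(data=archive["data"], fs=float(archive["fs"]),
                                     epoch_count=int(archive["epoch_count"]))
    data = pd.read_csv(path, header=None).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RegionalRecording(data=data, fs=float(meta["fs"]),
                             epoch_count=int(meta.get("epoch_count", 1)))


# ---------------------------------------------------------------------------
# run configuration


class BandConfig(BaseModel):
    name: str
    f_lo: float
    f_hi: float
    n_points: int = 10

    def to_spec(self) -> BandSpec:
        return BandSpec(self.name, self.f_lo, self.f_hi, self.n_points)


class SBIConfig(BaseModel):
    rounds: int = Field(3, ge=1)
    sims_per_round: int = Field(1000, ge=1)
    noise_sd: float = Field(1.0, ge=0.0)
    annealing_iters: int = Field(200, ge=1)


class NullConfig(BaseModel):
    kind: str = "shuffle"
    n: int = Field(1000, ge=1)


class RunConfig(BaseModel):
    """Declarative configuration for the pipeline commands.

    All randomness fans out deterministically from ``seed``. Parameter
    bounds default to the admissible box and must satisfy lo < hi.
    """

    sc_dir: Optional[str] = None
    fc_path: Optional[str] = None
    pred_path: Optional[str] = None
    timeseries_path: Optional[str] = None
    benchmark_method: str = "direct"
    out_dir: str = "sgmfc_out"
    bands: List[BandConfig] = Field(default_factory=lambda: [
        BandConfig(name=b.name, f_lo=b.f_lo, f_hi=b.f_hi, n_points=b.n_points)
        for b in DEFAULT_BANDS
    ])
    bounds: dict = Field(default_factory=lambda: {
        k: list(v) for k, v in PARAM_BOUNDS.items()})
    sbi: SBIConfig = Field(default_factory=SBIConfig)
    null: NullConfig = Field(default_factory=NullConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check_bounds(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds.{name}: lower bound {lo} must be < {hi}")
        return self

    def band_specs(self) -> Tuple[BandSpec, ...]:
        return tuple(b.to_spec() for b in self.bands)


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as handle:
        payload = yaml.safe_load(handle) or {}
    return RunConfig(**payload)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
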