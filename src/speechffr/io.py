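"""Reading and writing the package's file formats.

Audio comes and goes as WAV (mono; integer PCM is rescaled to [-1, 1]).
Waveforms, neural recordings and correlation functions are columnar numeric
text with a one-line ``# key=value`` header, so every artifact remains
greppable and diffable.  Flat TOML files carry run configuration.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .fwave import AudioSignal, FundamentalWaveform
from .neuro import NeuralRecording
from .xcorr import ComplexCorrelation


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono WAV file; integer PCM is scaled to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioSignal(data, float(rate))


def write_wav(path: str | Path, audio: AudioSignal) -> None:
    peak = np.max(np.abs(audio.samples)) or 1.0
    wavfile.write(str(path), int(round(audio.rate)),
                  (audio.samples / peak).astype(np.float32))


def _read_header(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        line = fh.readline()
    if line.startswith("#"):
        for token in line[1:].split():
            if "=" in token:
                key, val = token.split("=", 1)
                meta[key] = float(val)
    return meta


def write_fwave(path: str | Path, fwave: FundamentalWaveform) -> None:
    """Waveform, quadrature and voicing mask as three numeric columns."""
    table = np.column_stack(
        [fwave.samples, fwave.quadrature, fwave.voicing_mask.astype(float)]
    )
    np.savetxt(path, table, fmt="%.9g",
               header=f"sample_rate={fwave.rate:g}", comments="# ")


def read_fwave(path: str | Path) -> FundamentalWaveform:
    meta = _read_header(Path(path))
    rate = meta.get("sample_rate", 8820.0)
    table = np.loadtxt(path)
    return FundamentalWaveform(
        table[:, 0], table[:, 1], table[:, 2] > 0.5, rate
    )


def write_neural(path: str | Path, rec: NeuralRecording) -> None:
    header = f"rate={rec.rate:g} stimulus_offset={rec.stimulus_offset:g}"
    np.savetxt(path, rec.channels.T, fmt="%.9g", header=header, comments="# ")


def read_neural(path: str | Path, rate: float | None = None) -> NeuralRecording:
    """Columnar numeric text (one column per channel) or a mono WAV."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        audio = read_wav(path)
        return NeuralRecording(audio.samples[None, :], audio.rate)
    meta = _read_header(path)
    table = np.loadtxt(path)
    channels = table[None, :] if table.ndim == 1 else table.T
    file_rate = meta.get("rate", rate)
    if file_rate is None:
        raise ValueError(f"{path}: no '# rate=' header and no --rate given")
    return NeuralRecording(
        channels, float(file_rate), meta.get("stimulus_offset", 0.0)
    )


def write_correlation(path: str | Path, corr: ComplexCorrelation) -> None:
    table = np.column_stack([corr.lags_ms, corr.values.real, corr.values.imag])
    np.savetxt(path, table, fmt="%.9g",
               header="lag_ms real imag", comments="# ")


def read_correlation(path: str | Path) -> ComplexCorrelation:
    table = np.loadtxt(path)
    return ComplexCorrelation(table[:, 0], table[:, 1] + 1j * table[:, 2])


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
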