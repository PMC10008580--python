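"""Sinusoidal positional encodings of absolute elapsed time.

Each row of dynamic data carries, besides the flat normalized-minutes column,
``n_pe`` (default 64) sinusoidal features of the raw time in minutes:

    column 2i   = sin(t / B^(2i / n_pe))
    column 2i+1 = cos(t / B^(2i / n_pe)),     i in [0, n_pe / 2)

with wavelength base ``B`` (default 10000).  Sines and cosines alternate, with
frequency decreasing as the column index grows.  Because the encoding of
``t + d`` is a fixed rotation of the encoding of ``t`` for any offset ``d``, a
downstream sequence model can reason about both relative and absolute time.
The position is the raw elapsed minutes, not the row index: the meaning of the
features is anchored to physical time, which is irregularly sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TemporalEncodingConfig:
    n_pe: int = 64
    base: float = 10000.0
    include_flat: bool = True

    def __post_init__(self) -> None:
        # n_pe = 0 disables the sinusoidal block entirely (the flat-time-only
        # ablation variant); otherwise an even count >= 2 is required.
        if self.n_pe != 0 and (self.n_pe < 2 or self.n_pe % 2 != 0):
            raise ValueError("n_pe must be 0 or an even number >= 2")
        if self.base <= 1:
            raise ValueError("base must be > 1")

    @property
    def n_temporal(self) -> int:
        return self.n_pe + int(self.include_flat)

    def column_names(self) -> list[str]:
        names = ["time_flat"] if self.include_flat else []
        for i in range(self.n_pe // 2):
            names.extend([f"pe_sin_{i:02d}", f"pe_cos_{i:02d}"])
        return names


def positional_encoding(
    times_min: np.ndarray, cfg: TemporalEncodingConfig | None = None
) -> np.ndarray:
    """(len, n_pe) matrix of alternating sin/cos features of time in minutes."""
    cfg = cfg or TemporalEncodingConfig()
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1:
        raise ValueError("times_min must be one-dimensional")
    if t.size and (not np.all(np.isfinite(t)) or np.any(t < 0)):
        raise ValueError("times must be finite and non-negative")

    i = np.arange(cfg.n_pe // 2)
    angular = t[:, None] / (cfg.base ** (2.0 * i / cfg.n_pe))[None, :]
    out = np.empty((t.size, cfg.n_pe), dtype=float)
    out[:, 0::2] = np.sin(angular)
    out[:, 1::2] = np.cos(angular)
    return out


def temporal_features(
    times_min: np.ndarray,
    normalizer=None,
    cfg: TemporalEncodingConfig | None = None,
) -> np.ndarray:
    """Concatenation [flat normalized minutes | positional encoding].

    The flat column is the elapsed minutes pushed through the normalizer's
    time transform (fitted on pooled training observation times); 65 columns
    by default.
    """
    cfg = cfg or TemporalEncodingConfig()
    t = np.asarray(times_min, dtype=float)
    pe = positional_encoding(t, cfg)
    if not cfg.include_flat:
        return pe
    if normalizer is None:
        raise ValueError("a fitted normalizer is required when include_flat is set")
    flat = normalizer.transform_time(t).reshape(-1, 1)
    return np.concatenate([flat, pe], axis=1)
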