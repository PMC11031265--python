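"""Measurement noise and multichannel-offset corruption.

Multichannel data-acquisition and amplifier electronics interfere so that
at each time step every detector of the ring array picks up the same
instantaneous gain.  The measurement model is

    p(q) = M(q) h + z(q) 1 + e,

with ``e ~ N(0, sigma^2 I)`` i.i.d. background noise and ``z(q) ~
N(0, beta^2)`` a per-time-step offset common to all channels (the ``1``
direction).  Per time step the detector covariance is therefore
``Sigma(q) = beta^2 1 1^T + sigma^2 I``.  The offset paints vertical
stripes on the sinogram and concentric rings on circular-geometry
reconstructions.

``sigma`` is set from a target SNR measured on the input sinogram (mean
power over all entries — the "measured" convention); ``beta`` is a free
parameter since it depends on the acquisition hardware, with stripes
prominent when ``sigma <= beta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import Sinogram

__all__ = ["NoiseSpec", "add_awgn", "add_channel_offset", "noise_sigma_for_snr"]

#: default offset-to-noise std ratio beta/sigma (offsets dominant over noise)
DEFAULT_OFFSET_RATIO = 3.0


@dataclass(frozen=True)
class NoiseSpec:
    """Corruption parameters: target SNR (dB), offset std, and seeds.

    With ``seed`` fixed the corruption is bit-reproducible; the AWGN and
    offset draws use distinct derived seeds so each is independently
    reproducible.
    """

    snr_db: float = 5.0
    offset_std: float | None = None  # None -> DEFAULT_OFFSET_RATIO * sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset_std is not None and self.offset_std < 0:
            raise ValueError("offset_std must be >= 0")

    @property
    def noise_seed(self) -> int:
        return (2 * self.seed) % (2**31)

    @property
    def offset_seed(self) -> int:
        return (2 * self.seed + 1) % (2**31)


def noise_sigma_for_snr(sino: Sinogram, snr_db: float) -> float:
    """Noise std giving the target SNR against the sinogram's mean power."""
    power = float(np.mean(sino.values**2))
    if power == 0.0:
        raise ValueError("cannot set an SNR against an all-zero sinogram")
    return float(np.sqrt(power / 10.0 ** (snr_db / 10.0)))


def add_awgn(sino: Sinogram, snr_db: float, seed: int) -> tuple[Sinogram, float]:
    """Add white Gaussian noise at the given SNR; returns (sinogram, sigma).

    ``sigma^2 = P_signal / 10^(snr_db/10)`` with ``P_signal`` the mean
    squared value over all entries of the input.  ``snr_db = inf`` is a
    no-op returning sigma 0.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return sino.with_values(sino.values.copy(), tag="noisy"), 0.0
    sigma = noise_sigma_for_snr(sino, snr_db)
    rng = np.random.default_rng(seed)
    noisy = sino.values + rng.normal(0.0, sigma, size=sino.values.shape)
    return sino.with_values(noisy, tag="noisy"), sigma


def add_channel_offset(sino: Sinogram, offset_std: float, seed: int) -> Sinogram:
    """Add one ``z(q) ~ N(0, offset_std^2)`` to all detectors per time step.

    The added component lies exactly in span{1} per time column, producing
    the vertical stripe pattern; ``offset_std = 0`` is a no-op.
    """
    if offset_std < 0:
        raise ValueError("offset_std must be >= 0")
    if offset_std == 0:
        return sino.with_values(sino.values.copy(), tag="corrupted")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, offset_std, size=sino.n_samples)  # one draw per column
    return sino.with_values(sino.values + z[None, :], tag="corrupted")
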