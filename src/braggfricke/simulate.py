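"""Forward simulator of the 20-fibre track-end absorbance measurement.

Stands in for the beamline: given a ground-truth yield profile G(Fe3+)(x) and
a depth-ELF curve, it produces per-fibre absorbance time series (and, on
request, raw 16-bit image stacks) with the statistical structure the inverse
analysis assumes — early-time absorbance growth proportional to the local
dose rate, saturation near the Fricke dose limit, Fe3+ diffusion along the
beam axis and out of the 8-mm beam cylinder, and heteroscedastic detector
noise applied in intensity space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .chemistry import FrickeSystem, effective_dose
from .materials import BeamSpec
from .stopping import DepthProfile, dose_rate_profile

__all__ = [
    "FibreArray",
    "AcquisitionSpec",
    "GroundTruth",
    "AbsorbanceRecord",
    "diffusion_displacement",
    "simulate_concentration_field",
    "render_absorbance",
    "render_image_stack",
    "records_to_table",
    "records_from_table",
    "FE3_DIFFUSION_COEFF",
]

#: Fe3+ diffusion coefficient in water at 25 C, m^2/s
FE3_DIFFUSION_COEFF = 6.07e-10


def diffusion_displacement(diff_coeff: float, t: float) -> float:
    """Mean 1-D diffusive displacement sqrt(4 D t / pi), in metres.

    With the Fe3+ coefficient 6.07e-10 m^2/s this gives ~28 um per second,
    the scale on which the irradiated cylinder boundary blurs.
    """
    if diff_coeff < 0 or t < 0:
        raise ValueError("D and t must be >= 0")
    return float(np.sqrt(4.0 * diff_coeff * t / np.pi))


@dataclass(frozen=True)
class FibreArray:
    """Mapping from fibre index to a depth interval along the beam axis.

    Fibre `n_fibres` (20) sits shallowest, at the beam entrance side of the
    observed window; fibre 1 is deepest. Each 250-um fibre images a
    fibre_diameter / magnification = 281.25 um wide interval of the sample;
    intervals are contiguous, half-open [x, x+w), starting `depth_offset` mm
    below the sample entrance.
    """

    n_fibres: int = 20
    fibre_diameter_um: float = 250.0
    magnification: float = 8.0 / 9.0
    depth_offset_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_fibres < 1:
            raise ValueError("need at least one fibre")
        if not (0 < self.magnification):
            raise ValueError("magnification must be positive")

    @property
    def interval_width_mm(self) -> float:
        return self.fibre_diameter_um / self.magnification / 1000.0

    def fibre_indices(self) -> np.ndarray:
        """Fibre labels ordered shallow to deep: n_fibres, ..., 1."""
        return np.arange(self.n_fibres, 0, -1)

    def depth_interval(self, fibre: int) -> tuple[float, float]:
        """Half-open [x0, x1) depth interval in mm for fibre label `fibre`."""
        if not 1 <= fibre <= self.n_fibres:
            raise ValueError(f"fibre index {fibre} out of 1..{self.n_fibres}")
        w = self.interval_width_mm
        k = self.n_fibres - fibre  # 0 for the shallowest fibre
        x0 = self.depth_offset_mm + k * w
        return (x0, x0 + w)

    def fibre_centres(self) -> np.ndarray:
        """Centre depths (mm), ordered shallow to deep like fibre_indices()."""
        w = self.interval_width_mm
        return self.depth_offset_mm + (np.arange(self.n_fibres) + 0.5) * w

    def fibre_of_depth(self, depth_mm: float) -> int | None:
        """Fibre label whose interval contains `depth_mm`, or None."""
        w = self.interval_width_mm
        k = int(np.floor((depth_mm - self.depth_offset_mm) / w))
        if 0 <= k < self.n_fibres:
            return self.n_fibres - k
        return None


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera timing and noise for one irradiation sequence."""

    frame_period: float = 0.1  # s, 100 ms integration
    duration: float = 60.0  # s
    beam_on_time: float = 2.0  # s
    noise_rel_intensity: float = 0.005  # relative sigma of I per frame
    flicker_rel: float = 0.0  # common-mode source flicker, relative sigma
    binning: int = 1

    def __post_init__(self) -> None:
        if self.frame_period <= 0:
            raise ValueError("frame period must be positive")
        if not 0 <= self.beam_on_time < self.duration:
            raise ValueError("beam_on_time must lie within [0, duration)")
        if self.binning not in (1, 2):
            raise ValueError("binning must be 1 or 2")

    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_period))
        return np.arange(n) * self.frame_period


@dataclass
class GroundTruth:
    """Known truth the simulator renders and the pipeline must recover."""

    yield_profile: np.ndarray  # G(Fe3+)(x) in mol/J on elf.depth_grid
    elf: DepthProfile
    beam: BeamSpec
    system: FrickeSystem = field(default_factory=FrickeSystem)
    diffusion_coeff: float = FE3_DIFFUSION_COEFF  # m^2/s
    path_length_cm: float = 0.8  # optical path = beam diameter
    #: the observable saturation onset tracks the classic Fricke dose limit
    #: (500 Gy), not the extended super-Fricke linearity bound; None keeps that.
    sat_dose_limit: float | None = None
    radial_loss: bool = True

    def __post_init__(self) -> None:
        self.yield_profile = np.broadcast_to(
            np.asarray(self.yield_profile, dtype=float), self.elf.depth_grid.shape
        ).copy()
        if np.any(self.yield_profile < 0):
            raise ValueError("yields must be >= 0")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion coefficient must be >= 0")


@dataclass
class AbsorbanceRecord:
    """One fibre's absorbance time series, baseline-referenced to pre-beam frames."""

    fibre: int
    times: np.ndarray
    absorbance: np.ndarray
    frame_period: float
    beam_on_time: float | None = None
    path_length_cm: float = 0.8

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance shapes differ")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")


def simulate_concentration_field(
    gt: GroundTruth, times: np.ndarray, saturate: bool = True
) -> np.ndarray:
    """Fe3+ concentration field C(x, t) in mol/L on (times, elf.depth_grid).

    Per frame the linear-regime increment G(x) * rho * dD/dt(x) * dt is added
    (attenuated by the saturation mapping's local slope once the accumulated
    dose approaches the Fricke limit), then 1-D diffusion along the beam axis
    is applied as a Gaussian kernel with reflecting boundaries (mass
    conserving), and radial escape from the 8-mm cylinder as the deterministic
    dilution (d / (d + 2 sqrt(4 D t / pi)))^2 of the expanding section.
    """
    times = np.asarray(times, dtype=float)
    dd = dose_rate_profile(gt.elf, gt.beam, gt.system.density)  # Gy/s
    rho = gt.system.density
    dx_m = gt.elf.grid_step * 1e-3
    limit = (
        gt.sat_dose_limit
        if gt.sat_dose_limit is not None
        else gt.system.dose_limit_fricke
    )

    c = np.zeros_like(gt.elf.depth_grid)
    dose = np.zeros_like(c)
    out = np.zeros((times.size, c.size))
    d_beam_m = gt.beam.diameter * 1e-3

    def radial_factor(t0, t1):
        if gt.diffusion_coeff == 0 or not gt.radial_loss:
            return 1.0
        r0 = d_beam_m + 2.0 * diffusion_displacement(gt.diffusion_coeff, t0)
        r1 = d_beam_m + 2.0 * diffusion_displacement(gt.diffusion_coeff, t1)
        return (r0 / r1) ** 2

    prev_t = times[0]
    for j, t in enumerate(times):
        dt = t - prev_t
        if dt > 0:
            # dose increment and saturation-attenuated production
            if saturate:
                slope = np.exp(-dose / _dsat(limit))
            else:
                slope = 1.0
            c = c + gt.yield_profile * rho * dd * dt * slope
            dose = dose + dd * dt
            # axial diffusion: Gaussian kernel, reflecting walls conserve mass
            if gt.diffusion_coeff > 0:
                sigma_m = np.sqrt(2.0 * gt.diffusion_coeff * dt)
                c = gaussian_filter1d(c, sigma_m / dx_m, mode="reflect")
                c = c * radial_factor(prev_t, t)
        out[j] = c
        prev_t = t
    return out


def _dsat(limit: float) -> float:
    from .chemistry import _saturation_dose

    return _saturation_dose(limit)


def render_absorbance(
    field: np.ndarray,
    times: np.ndarray,
    gt: GroundTruth,
    fa: FibreArray,
    acq: AcquisitionSpec,
    rng: np.random.Generator | None = None,
) -> list[AbsorbanceRecord]:
    """Per-fibre absorbance records from a concentration field.

    A(t) = epsilon * l * <C> over each fibre's 281.25-um interval. If the
    acquisition specifies noise, it is applied in transmitted-intensity space
    (I = I0 10^-A, multiplicative shot-like noise and common-mode flicker),
    then A is recomputed, so the absorbance noise is heteroscedastic exactly
    as in real transmission data.
    """
    times = np.asarray(times, dtype=float)
    grid = gt.elf.depth_grid
    eps_l = gt.system.epsilon_304 * gt.path_length_cm
    records = []
    noisy = rng is not None and (acq.noise_rel_intensity > 0 or acq.flicker_rel > 0)
    if noisy:
        flicker = 1.0 + acq.flicker_rel * rng.standard_normal(times.size)
    for fibre in fa.fibre_indices():
        x0, x1 = fa.depth_interval(int(fibre))
        mask = (grid >= x0) & (grid < x1)
        if not mask.any():
            raise ValueError(
                f"fibre {fibre} interval [{x0:.3f}, {x1:.3f}) mm outside the "
                "simulated depth grid"
            )
        a = eps_l * field[:, mask].mean(axis=1)
        if noisy:
            i_rel = 10.0 ** (-a)
            i_rel = i_rel * flicker * (
                1.0 + acq.noise_rel_intensity * rng.standard_normal(a.size)
            )
            i_rel = np.clip(i_rel, 1e-12, None)
            a = -np.log10(i_rel)
        records.append(
            AbsorbanceRecord(
                fibre=int(fibre),
                times=times,
                absorbance=a,
                frame_period=acq.frame_period,
                beam_on_time=acq.beam_on_time,
                path_length_cm=gt.path_length_cm,
            )
        )
    return records


def render_image_stack(
    records: list[AbsorbanceRecord],
    acq: AcquisitionSpec,
    i0: float = 30000.0,
    band_height: int = 8,
    width: int = 64,
) -> tuple[np.ndarray, dict]:
    """Encode absorbance records as a 16-bit grayscale frame sequence.

    Each fibre occupies a known horizontal row band whose mean intensity is
    I = I0 10^-A; a JSON-serialisable sidecar records the band -> fibre map so
    the inverse pipeline can be exercised end-to-end from pixels.
    """
    if not records:
        raise ValueError("no records to render")
    times = records[0].times
    for r in records:
        if r.times.shape != times.shape or not np.allclose(r.times, times):
            raise ValueError("records must share a common time grid")
    bh = max(band_height // acq.binning, 1)
    w = max(width // acq.binning, 1)
    n_rows = bh * len(records)
    stack = np.zeros((times.size, n_rows, w), dtype=np.uint16)
    bands = {}
    # shallowest fibre (highest label) on top, mirroring the camera image
    ordered = sorted(records, key=lambda r: -r.fibre)
    for k, rec in enumerate(ordered):
        inten = i0 * 10.0 ** (-rec.absorbance)
        if np.any(inten > 65535):
            warnings.warn("intensity overflow; clipping to 16-bit range")
            inten = np.clip(inten, 0, 65535)
        rows = (k * bh, (k + 1) * bh)
        stack[:, rows[0] : rows[1], :] = np.rint(inten)[:, None, None].astype(
            np.uint16
        )
        bands[str(rec.fibre)] = {"row_start": rows[0], "row_stop": rows[1]}
    sidecar = {
        "i0": i0,
        "frame_period": acq.frame_period,
        "beam_on_time": acq.beam_on_time,
        "binning": acq.binning,
        "path_length_cm": records[0].path_length_cm,
        "bands": bands,
    }
    return stack, sidecar


def simulate_run(
    gt: GroundTruth,
    fa: FibreArray | None = None,
    acq: AcquisitionSpec | None = None,
    rng: np.random.Generator | None = None,
    saturate: bool = True,
) -> list[AbsorbanceRecord]:
    """Full acquisition: flat pre-beam baseline, then the evolving field.

    The concentration field is integrated from beam-on; frames before
    `acq.beam_on_time` read zero absorbance (plus noise if an rng is given).
    """
    if fa is None:
        fa = FibreArray()
    if acq is None:
        acq = AcquisitionSpec()
    times = acq.times()
    post = times >= acq.beam_on_time
    t_rel = times[post] - acq.beam_on_time
    if t_rel.size == 0 or t_rel[0] > 0:
        t_rel = np.concatenate(([0.0], t_rel))
        padded = True
    else:
        padded = False
    field_post = simulate_concentration_field(
        gt, t_rel, saturate=saturate
    )
    if padded:
        field_post = field_post[1:]
    field = np.zeros((times.size, gt.elf.depth_grid.size))
    field[post] = field_post
    return render_absorbance(field, times, gt, fa, acq, rng=rng)


def records_to_table(records: list[AbsorbanceRecord]):
    """Tidy (fibre, time_s, absorbance) DataFrame for the exchange format."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {"fibre": r.fibre, "time_s": r.times, "absorbance": r.absorbance}
        )
        for r in sorted(records, key=lambda r: -r.fibre)
    ]
    return pd.concat(frames, ignore_index=True)


def records_from_table(
    table, frame_period: float | None = None, beam_on_time: float | None = None
) -> list[AbsorbanceRecord]:
    """Rebuild AbsorbanceRecords from a tidy (fibre, time_s, absorbance) table."""
    records = []
    for fibre, grp in table.groupby("fibre"):
        t = grp["time_s"].to_numpy()
        order = np.argsort(t)
        t = t[order]
        fp = frame_period if frame_period is not None else float(np.median(np.diff(t)))
        records.append(
            AbsorbanceRecord(
                fibre=int(fibre),
                times=t,
                absorbance=grp["absorbance"].to_numpy()[order],
                frame_period=fp,
                beam_on_time=beam_on_time,
            )
        )
    return sorted(records, key=lambda r: -r.fibre)


def write_stack(path_tiff, path_sidecar, stack: np.ndarray, sidecar: dict) -> None:
    """Write the multi-page TIFF and its JSON geometry sidecar."""
    import tifffile

    tifffile.imwrite(path_tiff, stack)
    with open(path_sidecar, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_stack(path_tiff, path_sidecar) -> tuple[np.ndarray, dict]:
    import tifffile

    with open(path_sidecar) as fh:
        sidecar = json.load(fh)
    return tifffile.imread(path_tiff), sidecar
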