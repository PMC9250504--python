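"""Head models and lead fields.

A lead field is the linear operator ``M`` (channels x sources) mapping unit
cortical source amplitudes to scalp potentials, ``y = M x + noise``.  This
module provides

* a deterministic, download-free fixture: electrodes and radially oriented
  dipoles placed quasi-uniformly on concentric spheres, with potentials from
  the analytic three-shell (brain / skull / scalp) series solution;
* an HDF5 reader/writer for lead-field archives, with a field-name mapping
  hook so externally published models (e.g. template FEM head models) can be
  loaded without conversion;
* montage masks restricting the *search space* of channel selection.  A mask
  never subsets the matrix itself: excluded channels are handled downstream
  by clamping their genes to zero, so the inverse operator keeps its shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from numpy.polynomial import legendre

__all__ = [
    "LeadField",
    "MontageMask",
    "InvalidGeometryError",
    "LeadFieldFormatError",
    "build_spherical_leadfield",
    "three_shell_radial_coeffs",
    "fibonacci_sphere",
    "save_leadfield",
    "load_leadfield",
    "make_montage_mask",
    "DEFAULT_SHELL_RADII",
    "DEFAULT_SHELL_CONDUCTIVITIES",
    "DEFAULT_SOURCE_RADIUS",
    "DEFAULT_SERIES_ORDER",
]

#: Shell radii in mm (brain, skull, scalp outer surface).
DEFAULT_SHELL_RADII = (80.0, 86.0, 92.0)
#: Shell conductivities in S/m (brain, skull, scalp).
DEFAULT_SHELL_CONDUCTIVITIES = (0.33, 0.0042, 0.33)
#: Radius of the spherical "cortex" carrying the sources, mm.
DEFAULT_SOURCE_RADIUS = 70.0
#: Truncation order of the Legendre series of the analytic potential.
DEFAULT_SERIES_ORDER = 80

_DIPOLE_MOMENT_AM = 1e-8  # 10 nA*m, a typical effective cortical patch dipole


class InvalidGeometryError(ValueError):
    """Raised for impossible shell geometry (e.g. non-increasing radii)."""


class LeadFieldFormatError(ValueError):
    """Raised when a lead-field archive is missing a required field."""


@dataclass(frozen=True)
class LeadField:
    """Fixed-orientation lead field with electrode and source geometry.

    Attributes
    ----------
    matrix : (d, n) ndarray
        Potential (uV) at each channel per unit source amplitude.
    channel_labels : list of str
        Unique channel names, length d.
    channel_positions : (d, 3) ndarray, mm.
    source_positions : (n, 3) ndarray, mm.
    source_orientations : (n, 3) ndarray
        Unit dipole orientations (fixed-orientation model).
    """

    matrix: np.ndarray
    channel_labels: list[str]
    channel_positions: np.ndarray
    source_positions: np.ndarray
    source_orientations: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "channel_positions", np.asarray(self.channel_positions, dtype=float))
        object.__setattr__(self, "source_positions", np.asarray(self.source_positions, dtype=float))
        object.__setattr__(self, "source_orientations", np.asarray(self.source_orientations, dtype=float))
        object.__setattr__(self, "channel_labels", [str(c) for c in self.channel_labels])
        d, n = self.matrix.shape
        if d < 2 or n < 2:
            raise ValueError(f"lead field needs d >= 2 channels and n >= 2 sources, got {d}x{n}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead-field matrix contains non-finite entries")
        if len(self.channel_labels) != d or self.channel_positions.shape != (d, 3):
            raise ValueError("channel metadata does not match matrix rows")
        if len(set(self.channel_labels)) != d:
            raise ValueError("channel labels are not unique")
        if self.source_positions.shape != (n, 3) or self.source_orientations.shape != (n, 3):
            raise ValueError("source metadata does not match matrix columns")
        norms = np.linalg.norm(self.source_orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("source orientations must be unit vectors (tol 1e-9)")
        center = self.source_positions.mean(axis=0)
        r_src = np.linalg.norm(self.source_positions - center, axis=1).max()
        r_chan = np.linalg.norm(self.channel_positions - center, axis=1)
        if np.any(r_chan < r_src - 1e-6):
            raise ValueError("channel positions must lie outside or on the source bounding sphere")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    def label_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass(frozen=True)
class MontageMask:
    """Boolean inclusion mask over the channels of a lead field."""

    name: str
    included: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "included", np.asarray(self.included, dtype=bool))
        if self.included.ndim != 1:
            raise ValueError("mask must be a 1-D boolean vector")
        if int(self.included.sum()) < 2:
            raise ValueError("a montage must include at least 2 channels")

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def fibonacci_sphere(n: int, radius: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Quasi-uniform points on a sphere (golden-angle lattice).

    If ``rng`` is given, the lattice is rigidly rotated by a random proper
    rotation so distinct seeds give distinct (but equally uniform) layouts.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    if rng is not None:
        a = rng.standard_normal((3, 3))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1.0
        pts = pts @ q.T
    return radius * pts


def three_shell_radial_coeffs(
    source_radius: float,
    shell_radii: Sequence[float],
    shell_conductivities: Sequence[float],
    n_terms: int,
) -> np.ndarray:
    """Legendre coefficients of the scalp potential of a unit radial dipole.

    For a radial dipole at radius ``b`` inside a concentric three-shell
    conductor, the potential at an outer-surface electrode is the series

        V(e) = sum_{l>=1} c_l P_l(cos gamma),

    with ``gamma`` the angle between dipole and electrode position vectors.
    Per degree l the five expansion constants of the piecewise solution
    (A1; A2, B2; A3, B3) are fixed by potential/current continuity at the two
    interior interfaces and zero radial current at the scalp surface; the
    linear 5x5 system is solved in radii normalized by the outer radius so
    powers r^l stay in range for large l.

    Returns coefficients ``c`` with ``c[0] = 0`` and ``c[l]`` for l=1..n_terms,
    scaled to uV for a 10 nA*m dipole.
    """
    r1, r2, r3 = (float(r) for r in shell_radii)
    s1, s2, s3 = (float(s) for s in shell_conductivities)
    if not (0.0 < r1 < r2 < r3):
        raise InvalidGeometryError(f"shell radii must be strictly increasing, got {shell_radii}")
    if min(s1, s2, s3) <= 0.0:
        raise InvalidGeometryError("conductivities must be positive")
    b = float(source_radius)
    if not 0.0 < b < r1:
        raise InvalidGeometryError(f"source radius {b} must lie inside the innermost shell ({r1})")
    a1, a2, beta = r1 / r3, r2 / r3, b / r3
    coeffs = np.zeros(n_terms + 1)
    for el in range(1, n_terms + 1):
        s_prim = el * beta ** (el - 1) / (4.0 * np.pi * s1)
        # unknowns: A1, A2, B2, A3, B3
        a = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at a1
        a[0] = [a1**el, -(a1**el), -(a1 ** -(el + 1)), 0.0, 0.0]
        rhs[0] = -s_prim * a1 ** -(el + 1)
        # radial current continuity at a1
        a[1] = [
            s1 * el * a1 ** (el - 1),
            -s2 * el * a1 ** (el - 1),
            s2 * (el + 1) * a1 ** -(el + 2),
            0.0,
            0.0,
        ]
        rhs[1] = s1 * (el + 1) * s_prim * a1 ** -(el + 2)
        # potential continuity at a2
        a[2] = [0.0, a2**el, a2 ** -(el + 1), -(a2**el), -(a2 ** -(el + 1))]
        # radial current continuity at a2
        a[3] = [
            0.0,
            s2 * el * a2 ** (el - 1),
            -s2 * (el + 1) * a2 ** -(el + 2),
            -s3 * el * a2 ** (el - 1),
            s3 * (el + 1) * a2 ** -(el + 2),
        ]
        # no current through the scalp surface (r = 1)
        a[4] = [0.0, 0.0, 0.0, el, -(el + 1)]
        sol = np.linalg.solve(a, rhs)
        coeffs[el] = sol[3] + sol[4]
    # physical scale: moment / R^2 (R in meters), expressed in uV
    scale = _DIPOLE_MOMENT_AM / (r3 * 1e-3) ** 2 * 1e6
    return coeffs * scale


def build_spherical_leadfield(
    n_channels: int,
    n_sources: int,
    shell_radii: Sequence[float] = DEFAULT_SHELL_RADII,
    shell_conductivities: Sequence[float] = DEFAULT_SHELL_CONDUCTIVITIES,
    seed: int = 0,
    source_radius: float = DEFAULT_SOURCE_RADIUS,
    n_terms: int = DEFAULT_SERIES_ORDER,
) -> LeadField:
    """Analytic three-shell spherical lead field with radial sources.

    Electrodes are placed quasi-uniformly on the outer shell and sources on
    an interior "cortical" sphere, both by a seeded Fibonacci lattice, so the
    result is bit-reproducible for a given seed.  Column ``j`` of the matrix
    is the scalp potential pattern of a unit-amplitude radial dipole at
    source ``j`` from the analytic concentric-shell series truncated at
    ``n_terms`` Legendre degrees.
    """
    if n_channels < 2:
        raise ValueError(f"need at least 2 channels, got {n_channels}")
    if n_sources < 2:
        raise ValueError(f"need at least 2 sources, got {n_sources}")
    coeffs = three_shell_radial_coeffs(source_radius, shell_radii, shell_conductivities, n_terms)
    rng = np.random.default_rng(seed)
    elec = fibonacci_sphere(n_channels, float(shell_radii[2]), rng)
    src = fibonacci_sphere(n_sources, float(source_radius), rng)
    ori = src / np.linalg.norm(src, axis=1, keepdims=True)
    cosg = np.clip((elec / float(shell_radii[2])) @ ori.T, -1.0, 1.0)
    matrix = legendre.legval(cosg, coeffs)
    labels = [f"E{i + 1:03d}" for i in range(n_channels)]
    return LeadField(matrix, labels, elec, src, ori)


# --------------------------------------------------------------------------
# archive I/O

_CANONICAL_FIELDS = {
    "M": "M",
    "chanlocs": "chanlocs",
    "chanlabels": "chanlabels",
    "srcpos": "srcpos",
    "srcori": "srcori",
}


def save_leadfield(leadfield: LeadField, path: str | Path) -> None:
    """Write a lead field to an HDF5 archive (datasets M, chanlocs,
    chanlabels, srcpos, srcori)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=leadfield.matrix)
        f.create_dataset("chanlocs", data=leadfield.channel_positions)
        f.create_dataset(
            "chanlabels",
            data=np.array(leadfield.channel_labels, dtype=h5py.string_dtype("utf-8")),
        )
        f.create_dataset("srcpos", data=leadfield.source_positions)
        f.create_dataset("srcori", data=leadfield.source_orientations)


def load_leadfield(
    path: str | Path,
    resolution: str = "high",
    field_map: dict[str, str] | None = None,
) -> LeadField:
    """Load a lead field from an HDF5 archive.

    The canonical layout is flat datasets ``M`` (d x n), ``chanlocs`` (d x 3),
    ``chanlabels`` (d strings), ``srcpos`` (n x 3), ``srcori`` (n x 3),
    optionally nested inside a group named after ``resolution`` (``"high"``
    for the dense source space used for forward simulation, ``"inverse"``
    for the coarser space used for inversion — keeping the two distinct
    avoids the "inverse crime" of inverting with the simulation grid).

    ``field_map`` maps the canonical names above to dataset paths inside the
    file, so externally published head-model archives can be read in place;
    a free-orientation leadfield stored as (d, n, 3) is collapsed to fixed
    orientation by projecting onto ``srcori``.  Missing ``srcori`` falls back
    to radial orientations computed from ``srcpos``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmap = dict(_CANONICAL_FIELDS)
    if field_map:
        fmap.update(field_map)
    with h5py.File(path, "r") as f:
        base = f[resolution] if resolution in f else f

        def get(name: str, required: bool = True):
            key = fmap[name]
            if key not in base:
                if required:
                    raise LeadFieldFormatError(f"archive {path.name} is missing dataset '{key}' ({name})")
                return None
            return np.asarray(base[key])

        m = get("M")
        chanlocs = get("chanlocs")
        labels_raw = get("chanlabels")
        srcpos = get("srcpos")
        srcori = get("srcori", required=False)
    labels = [x.decode() if isinstance(x, bytes) else str(x) for x in labels_raw]
    if srcori is None:
        srcori = srcpos / np.linalg.norm(srcpos, axis=1, keepdims=True)
    if m.ndim == 3:  # free-orientation (d, n, 3): project onto fixed orientations
        m = np.einsum("dnk,nk->dn", m, srcori)
    return LeadField(m, labels, chanlocs, srcpos, srcori)


# --------------------------------------------------------------------------
# montages

_MONTAGE_FILES = {"sub128": "sub128.txt", "sub60": "sub60.txt"}


def _read_montage_labels(name: str) -> list[str]:
    text = resources.files("eegsel.data").joinpath(_MONTAGE_FILES[name]).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def make_montage_mask(leadfield: LeadField, subset_spec: str | Sequence[str]) -> MontageMask:
    """Build a channel-inclusion mask from a named subset or a label list.

    ``"full"`` includes every channel; ``"sub128"``/``"sub60"`` are the
    packaged quasi-uniform sub-montages of the default 231-channel fixture
    (shipped as one-label-per-line text files); any other sequence is taken
    as an explicit list of channel labels.
    """
    if isinstance(subset_spec, str):
        if subset_spec == "full":
            return MontageMask("full", np.ones(leadfield.n_channels, dtype=bool))
        if subset_spec in _MONTAGE_FILES:
            labels = _read_montage_labels(subset_spec)
            name = subset_spec
        else:
            raise KeyError(f"unknown montage name {subset_spec!r}; use 'full', 'sub128', 'sub60' or a label list")
    else:
        labels = list(subset_spec)
        name = f"custom{len(labels)}"
    index = {lab: i for i, lab in enumerate(leadfield.channel_labels)}
    missing = [lab for lab in labels if lab not in index]
    if missing:
        raise KeyError(f"labels not present in the lead field: {missing}")
    mask = np.zeros(leadfield.n_channels, dtype=bool)
    for lab in labels:
        mask[index[lab]] = True
    return MontageMask(name, mask)
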