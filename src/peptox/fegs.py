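"""Graphical + statistical sequence features (modified FEGS encoder).

Each physicochemical property scale places the 20 amino acids on the
lateral surface of a right circular cone: the scale's values are sorted
ascending, cumulatively summed, and affinely rescaled to [1, 20] (the
zeta series), and an amino acid's zeta value fixes both its height along
the cone axis and its angle around it.  A sequence then traces a 3D curve
— one step per residue, each step displaced by the residue's cone
coordinate plus the running pair coordinate weighted by the prefix
dipeptide frequency — and the leading eigenvalue of the curve's
point-to-point Euclidean distance matrix summarizes the curve as one
scalar per property.  The final feature vector concatenates the
per-property eigenvalues with 20 amino-acid and 400 dipeptide
frequencies; with the packaged 158-property table that is 578 numbers.

Cone geometry, the pair-coordinate rule (midpoint) and the curve-step
rule are this package's documented parametrization; see docs/methods.md.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse.linalg

from .sequence_io import AA_INDEX, STANDARD_AA

#: ordered list of the 400 dipeptides, row-major in alphabetical code order
DIPEPTIDES = [a + b for a in STANDARD_AA for b in STANDARD_AA]

_PACKAGED_TABLE = "aaindex1_synthetic_158.tsv"


class PropertyTableError(ValueError):
    """Raised for malformed or non-finite property data."""


@dataclass(frozen=True)
class PropertyTable:
    """AAindex1-style table: one numeric value per amino acid per property.

    ``values`` has shape (n_properties, 20) with columns in alphabetical
    one-letter-code order; feature order downstream follows the row order
    of ``properties``.
    """

    properties: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.properties), 20):
            raise PropertyTableError(
                f"expected ({len(self.properties)}, 20) values, got {values.shape}"
            )
        for name, row in zip(self.properties, values):
            if not np.all(np.isfinite(row)):
                raise PropertyTableError(f"non-finite values in property {name!r}")
        object.__setattr__(self, "values", values)

    @property
    def n_properties(self) -> int:
        return len(self.properties)

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [aa for aa in STANDARD_AA if aa not in df.columns]
        if missing:
            raise PropertyTableError(f"property table missing residue columns {missing}")
        return cls(tuple(df.index.astype(str)), df[list(STANDARD_AA)].to_numpy())

    @classmethod
    def packaged(cls) -> "PropertyTable":
        """The packaged 158-property table (synthetic AAindex1 stand-in)."""
        ref = importlib.resources.files("peptox.data").joinpath(_PACKAGED_TABLE)
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class ConeParams:
    """Right-circular-cone geometry shared by all properties.

    Apex at the origin, axis +z, ``height`` to the base plane, ``radius``
    of the base circle.  A zeta value z in [1, 20] maps to the surface
    point at fraction t = z/20 along the axis and angle 2*pi*z/20 around
    it.
    """

    radius: float = 1.0
    height: float = 1.0

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("cone radius and height must be positive")


@dataclass(frozen=True)
class ScaledSeries:
    """The zeta series: cumulative sums of sorted property values rescaled
    to [1, 20], plus the amino-acid permutation that produced it."""

    zeta: np.ndarray
    ordering: tuple[str, ...]


def compute_scaled_series(property_values: np.ndarray, name: str = "?") -> ScaledSeries:
    """Sort ascending (ties alphabetical), cumsum, rescale min->1 max->20."""
    values = np.asarray(property_values, dtype=np.float64)
    if values.shape != (20,):
        raise PropertyTableError(f"property {name!r}: expected 20 values, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise PropertyTableError(f"property {name!r}: non-finite values")
    order = np.lexsort((np.arange(20), values))  # stable: alphabetical tie-break
    cum = np.cumsum(values[order])
    lo, hi = cum.min(), cum.max()
    if hi == lo:  # constant cumulative series (all values zero)
        zeta = np.linspace(1.0, 20.0, 20)
    else:
        zeta = 1.0 + 19.0 * (cum - lo) / (hi - lo)
    ordering = tuple(STANDARD_AA[i] for i in order)
    return ScaledSeries(zeta=zeta, ordering=ordering)


def residue_coordinates(series: ScaledSeries, cone: ConeParams = ConeParams()) -> np.ndarray:
    """Place the 20 amino acids on the cone surface from their zeta values.

    Returns (20, 3) coordinates indexed alphabetically by one-letter code.
    Point for zeta value z: t = z/20, angle = 2*pi*z/20,
    (radius*t*cos, radius*t*sin, height*t) — on the cone surface
    x^2 + y^2 = (radius*z_axis/height)^2 by construction.
    """
    coords = np.zeros((20, 3))
    for aa, z in zip(series.ordering, series.zeta):
        t = z / 20.0
        theta = 2.0 * np.pi * z / 20.0
        coords[AA_INDEX[aa]] = (
            cone.radius * t * np.cos(theta),
            cone.radius * t * np.sin(theta),
            cone.height * t,
        )
    return coords


def pair_coordinates(coord_map: np.ndarray) -> np.ndarray:
    """Midpoint rule: coordinate of ordered pair (a, b) is (C_a + C_b)/2.

    Input (20, 3) single-residue coordinates; output (400, 3) indexed by
    :data:`DIPEPTIDES` order (20*i + j for pair (i, j)).
    """
    coord_map = np.asarray(coord_map, dtype=np.float64)
    if coord_map.shape != (20, 3):
        raise ValueError(f"expected (20, 3) coordinates, got {coord_map.shape}")
    return (coord_map[:, None, :] + coord_map[None, :, :]).reshape(400, 3) / 2.0


def prefix_pair_frequencies(sequence: str) -> np.ndarray:
    """f_i for i = 2..N: frequency of the adjacent pair (s_{i-1}, s_i)
    among the i-1 adjacent pairs of the first i residues.

    Returns an array of length N whose first entry (i = 1, no pair) is 0.
    """
    n = len(sequence)
    f = np.zeros(n)
    counts: dict[tuple[int, int], int] = {}
    for i in range(1, n):
        pair = (AA_INDEX[sequence[i - 1]], AA_INDEX[sequence[i]])
        counts[pair] = counts.get(pair, 0) + 1
        f[i] = counts[pair] / i  # i pairs seen in the (i+1)-residue prefix
    return f


def build_curve(
    sequence: str,
    coords: np.ndarray,
    pair_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Trace the 3D graphical curve of a sequence under one property.

    The curve starts at the origin (S_0); step i adds the residue's cone
    coordinate plus the pair coordinate of (s_{i-1}, s_i) weighted by the
    prefix pair frequency f_i:

        S_i = S_{i-1} + C(s_i) + f_i * P(s_{i-1}, s_i),   f_1 = 0.

    Returns (N + 1, 3) points.
    """
    if not sequence:
        raise ValueError("cannot build a curve for an empty sequence")
    for ch in sequence:
        if ch not in AA_INDEX:
            raise KeyError(f"residue {ch!r} absent from the property table alphabet")
    if pair_coords is None:
        pair_coords = pair_coordinates(coords)
    idx = np.array([AA_INDEX[ch] for ch in sequence])
    f = prefix_pair_frequencies(sequence)
    steps = coords[idx].copy()  # (N, 3)
    if len(sequence) > 1:
        pair_idx = idx[:-1] * 20 + idx[1:]
        steps[1:] += f[1:, None] * pair_coords[pair_idx]
    curve = np.zeros((len(sequence) + 1, 3))
    np.cumsum(steps, axis=0, out=curve[1:])
    return curve


def distance_matrix(curve: np.ndarray) -> np.ndarray:
    """L x L Euclidean distances between curve points; hollow symmetric."""
    curve = np.asarray(curve, dtype=np.float64)
    diff = curve[:, None, :] - curve[None, :, :]
    M = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(M, 0.0)
    return M


def leading_eigenvalue(M: np.ndarray, dense_cutoff: int = 512) -> float:
    """Largest eigenvalue of a symmetric matrix (Perron root for the
    non-negative distance matrices used here).

    Uses a dense symmetric eigensolver up to ``dense_cutoff``, an
    iterative Lanczos solver above it.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix is not symmetric within 1e-8")
    if M.shape[0] == 1:
        return float(M[0, 0])
    if M.shape[0] <= dense_cutoff:
        return float(np.linalg.eigvalsh(M)[-1])
    return float(scipy.sparse.linalg.eigsh(M, k=1, which="LA", return_eigenvectors=False)[0])


def composition_features(sequence: str) -> np.ndarray:
    """20 amino-acid frequencies then 400 dipeptide frequencies.

    Each block is normalized by its own observation count; a length-1
    sequence has an all-zero dipeptide block.
    """
    if not sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    idx = np.array([AA_INDEX[ch] for ch in sequence])
    aa_freq = np.bincount(idx, minlength=20).astype(np.float64) / len(sequence)
    dipep = np.zeros(400)
    if len(sequence) > 1:
        pair_idx = idx[:-1] * 20 + idx[1:]
        dipep = np.bincount(pair_idx, minlength=400).astype(np.float64) / (len(sequence) - 1)
    return np.concatenate([aa_freq, dipep])


@dataclass
class FegsEncoder:
    """Full modified-FEGS pipeline: sequence -> per-property eigenvalues
    + composition block, concatenated in table property order.

    Residue and pair coordinates are precomputed once per table.
    """

    table: PropertyTable = field(default_factory=PropertyTable.packaged)
    cone: ConeParams = ConeParams()

    def __post_init__(self):
        coords = np.zeros((self.table.n_properties, 20, 3))
        for p, name in enumerate(self.table.properties):
            series = compute_scaled_series(self.table.values[p], name=name)
            coords[p] = residue_coordinates(series, self.cone)
        self._coords = coords
        self._pair_coords = np.stack([pair_coordinates(c) for c in coords])

    @property
    def n_features(self) -> int:
        return self.table.n_properties + 420

    def feature_names(self) -> list[str]:
        return (
            [f"eig_{p}" for p in self.table.properties]
            + [f"freq_{aa}" for aa in STANDARD_AA]
            + [f"dipep_{d}" for d in DIPEPTIDES]
        )

    def curves(self, sequence: str) -> np.ndarray:
        """All per-property curves at once, shape (n_properties, N + 1, 3)."""
        for ch in sequence:
            if ch not in AA_INDEX:
                raise KeyError(f"residue {ch!r} absent from the property table alphabet")
        idx = np.array([AA_INDEX[ch] for ch in sequence])
        f = prefix_pair_frequencies(sequence)
        steps = self._coords[:, idx, :].copy()  # (P, N, 3)
        if len(sequence) > 1:
            pair_idx = idx[:-1] * 20 + idx[1:]
            steps[:, 1:, :] += f[1:, None] * self._pair_coords[:, pair_idx, :]
        curves = np.zeros((steps.shape[0], len(sequence) + 1, 3))
        np.cumsum(steps, axis=1, out=curves[:, 1:, :])
        return curves

    def eigenvalue_block(self, sequence: str) -> np.ndarray:
        curves = self.curves(sequence)
        diff = curves[:, :, None, :] - curves[:, None, :, :]
        M = np.sqrt((diff**2).sum(axis=-1))  # (P, L, L)
        if M.shape[1] <= 512:
            return np.linalg.eigvalsh(M)[:, -1]
        return np.array([leading_eigenvalue(m) for m in M])

    def encode(self, sequence: str) -> np.ndarray:
        """The FEGS feature vector; length n_properties + 420 (578 packaged)."""
        return np.concatenate([self.eigenvalue_block(sequence), composition_features(sequence)])

    def encode_many(self, sequences: list[str]) -> np.ndarray:
        return np.stack([self.encode(s) for s in sequences])


def fegs_vector(sequence: str, table: PropertyTable | None = None) -> np.ndarray:
    """Convenience wrapper: one-off encoding of a single sequence."""
    encoder = FegsEncoder(table=table) if table is not None else FegsEncoder()
    return encoder.encode(sequence)
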