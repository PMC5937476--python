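"""Synthetic backbone traces with controllable coarse 3-D shape.

Real enzyme structures are bulky to ship and slow to download, but the
classifier consumes nothing except backbone point clouds. This module
generates toy traces from six parametric shape families — straight rod,
helix, planar ring, space-filling globule, ellipsoidal shell, and a
two-lobed dumbbell — that are cleanly separable by overall shape, the
very signal a volumetric classifier exploits. Mapping the families onto
EC classes 1-6 yields a fully synthetic labeled dataset on which every
stage of the pipeline, including a scaled-down training run, can be
exercised end to end.

Traces emit four backbone atoms per residue (names cycling N, CA, C, O)
spaced roughly 1.5 Å along the family's curve — close to a real
backbone's inter-atom spacing, and dense enough that a 32-voxel grid at
R_max = 40 Å stays contiguous without interpolation. True peptide
geometry is *not* modelled: the representation uses only point positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .dataset import LabeledSample, N_CLASSES
from .structure_io import BackboneTrace

__all__ = [
    "FAMILIES",
    "FixtureSpec",
    "generate_trace",
    "residues_for_spacing",
    "write_pdb",
    "generate_labeled_dataset",
]

#: Shape families in EC-class order (family k -> EC class k+1).
FAMILIES = ("straight", "helix", "ring", "globule", "ellipsoid", "two_lobe")

_ATOM_CYCLE = ("N", "CA", "C", "O")
_TARGET_SPACING = 1.5  # Å between consecutive emitted atoms


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic trace.

    ``scale`` (Å) bounds the radius of the emitted cloud; ``noise_sd``
    is the s.d. of isotropic Gaussian jitter added per atom.
    """

    family: str
    n_residues: int = 40
    scale: float = 30.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _loxodrome(n: int, turns: float) -> np.ndarray:
    """Unit-sphere spiral from pole to pole with the given winding count."""
    t = np.linspace(0.0, 1.0, n)
    theta = np.arccos(1.0 - 2.0 * t)  # polar angle, uniform in cos
    phi = 2.0 * np.pi * turns * t
    return np.column_stack([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])


def _dense_curve(family: str, scale: float, rng: np.random.Generator,
                 n_dense: int = 4000) -> np.ndarray:
    """Dense polyline tracing the family's shape, radius <= ``scale``.

    Per-sample shape jitter (overall size +/-10%, winding counts +/-10%)
    gives within-class variability beyond coordinate noise.
    """
    size = scale * rng.uniform(0.9, 1.1)
    wind = rng.uniform(0.9, 1.1)
    t = np.linspace(0.0, 1.0, n_dense)
    if family == "straight":
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        return np.outer((2.0 * t - 1.0) * size, u)
    if family == "helix":
        r = 0.35 * size
        turns = 5.0 * wind
        angle = 2.0 * np.pi * turns * t
        z = (2.0 * t - 1.0) * 0.85 * size
        return np.column_stack([r * np.cos(angle), r * np.sin(angle), z])
    if family == "ring":
        angle = 2.0 * np.pi * t
        r = 0.9 * size
        return np.column_stack([r * np.cos(angle), r * np.sin(angle),
                                np.zeros_like(angle)])
    if family == "globule":
        # spiral whose radius grows as t^(1/3): uniform volume filling
        radii = size * np.cbrt(t)
        return radii[:, None] * _loxodrome(n_dense, 6.0 * wind)
    if family == "ellipsoid":
        return _loxodrome(n_dense, 6.0 * wind) * (size * np.array([1.0, 0.55, 0.3]))
    if family == "two_lobe":
        half = n_dense // 2
        lobe_r = 0.42 * size
        offset = np.array([0.55 * size, 0.0, 0.0])
        lobe1 = lobe_r * _loxodrome(half, 4.0 * wind) - offset
        lobe2 = lobe_r * _loxodrome(n_dense - half, 4.0 * wind) + offset
        return np.concatenate([lobe1, lobe2], axis=0)
    raise ValueError(f"unknown family {family!r}")


def _arc_resample(polyline: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline at n equidistant arc-length positions."""
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_points)
    out = np.empty((n_points, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, polyline[:, d])
    return out


def residues_for_spacing(family: str, scale: float = 30.0,
                         spacing: float = _TARGET_SPACING) -> int:
    """Residue count giving ~``spacing`` Å between consecutive atoms."""
    curve = _dense_curve(family, scale, np.random.default_rng(0))
    length = float(np.linalg.norm(np.diff(curve, axis=0), axis=1).sum())
    return max(2, round((length / spacing + 1) / len(_ATOM_CYCLE)))


def generate_trace(spec: FixtureSpec) -> BackboneTrace:
    """Deterministic synthetic backbone trace for the given spec."""
    rng = np.random.default_rng(spec.seed)
    n_atoms = len(_ATOM_CYCLE) * spec.n_residues
    coords = _arc_resample(_dense_curve(spec.family, spec.scale, rng), n_atoms)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(scale=spec.noise_sd, size=coords.shape)
    return BackboneTrace(
        structure_id=f"{spec.family}_{spec.seed:05d}",
        residue_indices=np.arange(n_atoms) // len(_ATOM_CYCLE),
        atom_names=tuple(_ATOM_CYCLE[i % len(_ATOM_CYCLE)]
                         for i in range(n_atoms)),
        coords=coords,
    )


def write_pdb(trace: BackboneTrace, path: str | Path) -> None:
    """Write a trace as a minimal single-chain PDB file (GLY residues)."""
    lines = []
    for i in range(trace.n_atoms):
        name = trace.atom_names[i]
        x, y, z = trace.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d}  {name:<3s} GLY A{int(trace.residue_indices[i]) + 1:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {name[0]:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_labeled_dataset(
    out_dir: str | Path,
    n_per_class: int = 10,
    seed: int = 0,
    scale: float = 30.0,
    noise_sd: float = 0.3,
    imbalance: tuple[int, ...] | None = None,
    write_files: bool = True,
) -> list[LabeledSample]:
    """Synthetic labeled dataset: shape families mapped to EC classes 1-6.

    Writes one minimal PDB file per sample plus a ``labels.csv``
    compatible with :func:`enzyvox.dataset.load_labels` (skipped when
    ``write_files`` is false, in which case samples carry in-memory
    traces). ``imbalance`` optionally multiplies the per-class sample
    count, e.g. ``(10, 10, 10, 2, 1, 1)``, to exercise the adapted class
    weights.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ratios = imbalance if imbalance is not None else (1,) * N_CLASSES
    if len(ratios) != N_CLASSES or any(r < 1 for r in ratios):
        raise ValueError(f"imbalance must be {N_CLASSES} positive integers")
    out_dir = Path(out_dir)
    if write_files:
        out_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(seed)
    samples: list[LabeledSample] = []
    rows = []
    for cls_idx, family in enumerate(FAMILIES):
        n_res = residues_for_spacing(family, scale)
        n_samples = n_per_class * ratios[cls_idx]
        children = root.spawn(N_CLASSES)[cls_idx].spawn(n_samples)
        for i, child in enumerate(children):
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            spec = FixtureSpec(family=family, n_residues=n_res, scale=scale,
                               noise_sd=noise_sd, seed=sub_seed)
            trace = replace(generate_trace(spec),
                            structure_id=f"{family}_{i:04d}")
            if write_files:
                path = out_dir / f"{trace.structure_id}.pdb"
                write_pdb(trace, path)
                source: Path | BackboneTrace = path
            else:
                source = trace
            samples.append(LabeledSample(trace.structure_id, cls_idx + 1, source))
            rows.append((trace.structure_id, cls_idx + 1))
    if write_files:
        import pandas as pd

        pd.DataFrame(rows, columns=["structure_id", "ec_class"]).to_csv(
            out_dir / "labels.csv", index=False)
    return samples
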