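"""Synthetic families of protein-like 3D models.

Each family shares a template backbone — a self-avoiding C-alpha trace with
3.8 A consecutive spacing and mixed helix/strand segments, decorated with
dummy N/C/O atoms per residue. Families differ by hinge (dihedral-level)
perturbations of a common base template, at an Angstrom scale set by
``between_divergence``; members within a family are the family template plus
per-atom Gaussian noise (``within_noise``) and a random rigid motion. The
default configuration emulates six annotated structural subsets of sizes
38/42/22/12/12/11 (137 models) at an immunoglobulin variable-domain scale of
~110 residues, with within-family noise 0.3 A and between-family divergence
3 A — a separation/noise ratio of 10.

Everything is deterministic given the seeds. Models can be written as legal
PDB files so fixtures exercise the real I/O path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import LabeledPartition
from .pdb_io import Atom, Chain, ProteinModel, Residue, write_pdb

__all__ = [
    "FamilySpec",
    "default_family_specs",
    "generate_template",
    "generate_dataset",
    "write_dataset",
    "DEFAULT_FAMILY_SIZES",
]

CA_SPACING = 3.8  # A, consecutive C-alpha distance
DEFAULT_FAMILY_SIZES = (38, 42, 22, 12, 12, 11)  # six annotated subsets, 137 models
DEFAULT_TEMPLATE_LENGTH = 110  # immunoglobulin variable-domain scale
DEFAULT_WITHIN_NOISE = 0.3  # A
DEFAULT_BETWEEN_DIVERGENCE = 3.0  # A

# Ideal helix geometry tuned so consecutive C-alphas are exactly 3.8 A apart:
# rise 1.5 A/residue, 100 deg/residue, radius 2.2790 A.
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)
_HELIX_RADIUS = np.sqrt(CA_SPACING**2 - _HELIX_RISE**2) / (2 * np.sin(_HELIX_TURN / 2))
# Planar strand zigzag: directions alternate +/- 28 deg about the segment axis,
# giving a CA(i), CA(i+2) spacing of about 6.7 A.
_STRAND_ANGLE = np.deg2rad(28.0)


@dataclass
class FamilySpec:
    family_id: str
    size: int
    template_length: int = DEFAULT_TEMPLATE_LENGTH
    within_noise: float = DEFAULT_WITHIN_NOISE
    between_divergence: float = DEFAULT_BETWEEN_DIVERGENCE
    seed: int = 0

    def validate(self) -> None:
        if self.size < 1:
            raise ValueError("family size must be >= 1")
        if self.within_noise < 0:
            raise ValueError("within_noise must be >= 0")


def default_family_specs(within_noise: float = DEFAULT_WITHIN_NOISE,
                         between_divergence: float = DEFAULT_BETWEEN_DIVERGENCE,
                         template_length: int = DEFAULT_TEMPLATE_LENGTH,
                         sizes=DEFAULT_FAMILY_SIZES) -> list[FamilySpec]:
    """Six families mirroring the annotated subset size distribution."""
    return [
        FamilySpec(family_id=f"F{i + 1}", size=s, template_length=template_length,
                   within_noise=within_noise, between_divergence=between_divergence,
                   seed=i)
        for i, s in enumerate(sizes)
    ]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _helix_segment(m: int) -> np.ndarray:
    """m C-alpha positions of an ideal helix along +z, starting at the origin."""
    t = np.arange(m)
    pts = np.stack([
        _HELIX_RADIUS * np.cos(_HELIX_TURN * t),
        _HELIX_RADIUS * np.sin(_HELIX_TURN * t),
        _HELIX_RISE * t,
    ], axis=1)
    return pts - pts[0]


def _strand_segment(m: int) -> np.ndarray:
    """m C-alpha positions of a planar zigzag strand starting at the origin."""
    pts = [np.zeros(3)]
    for i in range(1, m):
        sign = 1.0 if i % 2 else -1.0
        step = CA_SPACING * np.array([
            np.cos(_STRAND_ANGLE), sign * np.sin(_STRAND_ANGLE), 0.0
        ])
        pts.append(pts[-1] + step)
    return np.array(pts)


def _generate_ca_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding mixed helix/strand C-alpha trace with 3.8 A spacing."""
    trace = []
    while len(trace) < length:
        remaining = length - len(trace)
        seg_len = min(int(rng.integers(6, 13)), remaining)
        segment_kind = "H" if rng.random() < 0.5 else "E"
        local = (_helix_segment(seg_len) if segment_kind == "H"
                 else _strand_segment(seg_len))
        placed = None
        for _ in range(60):
            R = _random_rotation(rng)
            pts = local @ R.T
            if trace:
                # Enter the new segment one bond length along its own first
                # direction so the junction spacing is exactly 3.8 A.
                if len(pts) > 1:
                    entry = pts[1] - pts[0]
                    entry /= np.linalg.norm(entry)
                else:
                    entry = R @ np.array([0.0, 0.0, 1.0])
                origin = trace[-1] + CA_SPACING * entry
                pts = pts + origin
            prior = np.array(trace[:-2]) if len(trace) > 2 else None
            if prior is not None and len(pts):
                dmin = np.min(np.linalg.norm(
                    pts[:, None, :] - prior[None, :, :], axis=2))
                if dmin < 3.0:
                    continue
            placed = pts
            break
        if placed is None:
            placed = pts  # accept the last attempt rather than loop forever
        trace.extend(list(placed))
    return np.array(trace[:length])


def _decorate_backbone(ca: np.ndarray) -> list[list[Atom]]:
    """Dummy N/CA/C/O atoms per residue around each C-alpha position."""
    n_res = len(ca)
    residues = []
    for i in range(n_res):
        prev_dir = (ca[i] - ca[i - 1]) if i > 0 else (ca[i] - ca[i + 1])
        next_dir = (ca[i + 1] - ca[i]) if i < n_res - 1 else (ca[i] - ca[i - 1])
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        perp = np.cross(prev_dir, next_dir)
        if np.linalg.norm(perp) < 1e-6:
            ref = np.array([0.0, 0.0, 1.0]) if abs(next_dir[2]) < 0.9 \
                else np.array([1.0, 0.0, 0.0])
            perp = np.cross(next_dir, ref)
        perp = perp / np.linalg.norm(perp)
        n_pos = ca[i] - 1.45 * prev_dir if i > 0 else ca[i] - 1.45 * next_dir
        c_pos = ca[i] + 1.52 * next_dir
        o_pos = c_pos + 1.23 * perp
        residues.append([
            Atom("N", "N", *map(float, n_pos)),
            Atom("CA", "C", *map(float, ca[i])),
            Atom("C", "C", *map(float, c_pos)),
            Atom("O", "O", *map(float, o_pos)),
        ])
    return residues


def _model_from_ca(model_id: str, ca: np.ndarray) -> ProteinModel:
    residues = [
        Residue(number=i + 1, name="ALA", atoms=atoms)
        for i, atoms in enumerate(_decorate_backbone(ca))
    ]
    return ProteinModel(model_id, [Chain("A", residues)])


def generate_template(length: int, seed: int) -> ProteinModel:
    """Deterministic protein-like template of ``length`` residues."""
    if length < 10:
        raise ValueError("template length must be >= 10")
    rng = np.random.default_rng(seed)
    ca = _generate_ca_trace(length, rng)
    return _model_from_ca(f"template_{seed}", ca)


def _hinge_perturb(model: ProteinModel, magnitude: float,
                   rng: np.random.Generator, n_hinges: int = 8) -> ProteinModel:
    """Rotate the chain downstream of random hinge residues.

    Hinge angles scale with ``magnitude`` (A): per-hinge sd of 0.05 rad per A
    of requested divergence, producing conformational differences at roughly
    that coordinate scale over a ~110-residue chain.
    """
    coords = model.coords()
    n_res = model.n_residues
    atoms_per_res = 4
    coords = coords.reshape(n_res, atoms_per_res, 3)
    angle_sd = 0.05 * magnitude
    candidates = np.arange(5, max(n_res - 5, 6))
    n_hinges = min(n_hinges, len(candidates))
    if n_hinges == 0 or magnitude == 0:
        return _model_from_ca(model.model_id, coords[:, 1, :])
    hinges = sorted(rng.choice(candidates, size=n_hinges, replace=False))
    for h in hinges:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(scale=angle_sd)
        c, s = np.cos(angle), np.sin(angle)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        pivot = coords[h, 1, :].copy()
        coords[h + 1:] = (coords[h + 1:] - pivot) @ R.T + pivot
    ca = coords[:, 1, :]
    return _model_from_ca(model.model_id, ca)


def generate_dataset(specs: list[FamilySpec] | None = None,
                     global_seed: int = 1):
    """Generate labelled families of models.

    Returns ``(models, truth)`` where truth is a :class:`LabeledPartition`
    mapping each model id to its family id. Fully deterministic given the
    global seed and the per-family seeds.
    """
    if specs is None:
        specs = default_family_specs()
    ids_seen = set()
    for spec in specs:
        spec.validate()
        if spec.family_id in ids_seen:
            raise ValueError(f"duplicate family id {spec.family_id!r}")
        ids_seen.add(spec.family_id)

    base = generate_template(specs[0].template_length, seed=global_seed)
    models = []
    ids, labels = [], []
    for fam_idx, spec in enumerate(specs):
        fam_rng = np.random.default_rng([global_seed, spec.seed, fam_idx])
        if spec.template_length != base.n_residues:
            fam_base = generate_template(spec.template_length,
                                         seed=global_seed + 1000 + fam_idx)
        else:
            fam_base = base
        fam_template = _hinge_perturb(fam_base, spec.between_divergence, fam_rng)
        template_coords = fam_template.coords().reshape(
            fam_template.n_residues, 4, 3)
        for member in range(spec.size):
            coords = template_coords.copy()
            if spec.within_noise > 0:
                coords = coords + fam_rng.normal(scale=spec.within_noise,
                                                 size=coords.shape)
            R = _random_rotation(fam_rng)
            t = fam_rng.uniform(-20.0, 20.0, size=3)
            coords = coords @ R.T + t
            model_id = f"{spec.family_id}_{member:03d}"
            ca = coords[:, 1, :]
            model = _model_from_ca(model_id, ca)
            # keep the noisy non-CA atoms rather than re-derived ones
            flat = coords.reshape(-1, 3)
            for atom_idx, (_, _, atom) in enumerate(model.iter_atoms()):
                atom.x, atom.y, atom.z = map(float, flat[atom_idx])
            models.append(model)
            ids.append(model_id)
            labels.append(spec.family_id)
    truth = LabeledPartition(ids=ids, labels=labels)
    truth.validate()
    return models, truth


def write_dataset(models: list[ProteinModel], truth: LabeledPartition,
                  directory: str | Path) -> None:
    """Write models as PDB files plus a (model_id, label) TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for model in models:
        write_pdb(model, directory / f"{model.model_id}.pdb")
    with open(directory / "labels.tsv", "w") as handle:
        for i, l in zip(truth.ids, truth.labels):
            handle.write(f"{i}\t{l}\n")
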