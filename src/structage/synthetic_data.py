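"""Synthetic templates and longitudinal cohorts with known ground truth.

Real structure templates (fixed triangulations in vertex correspondence
across subjects) are emulated by sphere-like meshes with the exact
per-structure node counts (powers of two, so pooling halves them cleanly),
placed at plausible anatomical positions and scaled so average edge lengths
match the sub-2 (subcortical) and sub-3 (cortical) spacing of real surface
templates.

Shape carries age: each template owns a small basis of smooth displacement
fields, and a scan's mesh is the base mesh plus basis displacements whose
amplitudes are affine in the subject's latent "effective age"

    effective_age = baseline_age + aging_pace * scan_time + age_offset

with diagnosis-trajectory-dependent offset and pace, plus smooth
basis-correlated noise.  Every generated cohort ships a truth table so
downstream estimates (diagnosis offsets, aging-pace ratios) can be scored
against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .gcnn import ScanDataset
from .mesh_graph import (
    TEMPLATE_NODE_COUNTS,
    SurfaceMesh,
    build_features,
    save_mesh,
)

__all__ = [
    "SyntheticTemplate",
    "SyntheticSubject",
    "CohortConfig",
    "SyntheticCohort",
    "make_template",
    "generate_scan_mesh",
    "generate_cohort",
    "write_cohort",
]

#: Approximate radii (arbitrary units standing in for mm) giving realistic
#: average edge lengths at the template node counts.
STRUCTURE_RADII = {
    "accumbens": 5.0,
    "amygdala": 8.0,
    "caudate": 12.0,
    "hippocampus": 15.0,
    "pallidum": 8.0,
    "putamen": 12.0,
    "thalamus": 15.0,
    "cortex": 60.0,
}

#: Structure center positions for the left hemisphere (x mirrored for R).
STRUCTURE_CENTERS = {
    "accumbens": (-8.0, 12.0, -8.0),
    "amygdala": (-22.0, -4.0, -18.0),
    "caudate": (-13.0, 10.0, 10.0),
    "hippocampus": (-27.0, -22.0, -12.0),
    "pallidum": (-19.0, -4.0, 0.0),
    "putamen": (-25.0, 2.0, 0.0),
    "thalamus": (-11.0, -18.0, 8.0),
    "cortex": (-45.0, 0.0, 20.0),
}

GROUPS = ("non_converter", "MCI_converter", "ADD_converter")
_GROUP_DIAGNOSIS = {
    "non_converter": "healthy",
    "MCI_converter": "MCI",
    "ADD_converter": "ADD",
}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n points quasi-uniformly covering the unit sphere (golden-angle
    lattice); all points lie on the convex hull, so the hull triangulation
    is a watertight mesh with exactly n vertices."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _harmonic_fields(directions: np.ndarray, n_fields: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth radial displacement fields from low-order polynomial
    harmonics of the unit direction, each normalized to unit RMS norm."""
    x, y, z = directions.T
    basis_scalars = np.stack(
        [
            x,
            y,
            z,
            x * y,
            y * z,
            z * x,
            x * x - y * y,
            3 * z * z - 1,
            x * y * z,
            x * (x * x - 3 * y * y),
        ]
    )
    fields = np.empty((n_fields, len(directions), 3))
    for m in range(n_fields):
        w = rng.normal(size=basis_scalars.shape[0])
        scalar = w @ basis_scalars
        disp = scalar[:, None] * directions  # radial displacement
        rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        fields[m] = disp / max(rms, 1e-12)
    return fields


@dataclass
class SyntheticTemplate:
    """Sphere-like stand-in for one structure's surface template."""

    structure_label: str
    hemisphere: str
    mesh: SurfaceMesh  # base mesh, Table-3 node count
    deformation_basis: np.ndarray  # (M, N, 3), unit RMS fields
    field_weights: np.ndarray  # (M,) per-field gain multipliers

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


def make_template(
    structure_label: str,
    hemisphere: str = "L",
    seed: int = 0,
    n_fields: int = 6,
) -> SyntheticTemplate:
    """Deterministic synthetic template with the exact per-structure node
    count and a seeded smooth deformation basis."""
    if structure_label not in TEMPLATE_NODE_COUNTS:
        raise ValueError(f"unknown structure {structure_label!r}")
    n = TEMPLATE_NODE_COUNTS[structure_label]
    # stable per-structure stream (builtin hash is salted across processes)
    struct_idx = sorted(TEMPLATE_NODE_COUNTS).index(structure_label)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, struct_idx, 0 if hemisphere == "L" else 1])
    )
    directions = _fibonacci_sphere(n)
    hull = ConvexHull(directions)
    radius = STRUCTURE_RADII[structure_label]
    center = np.array(STRUCTURE_CENTERS[structure_label])
    if hemisphere == "R":
        center = center * np.array([-1.0, 1.0, 1.0])
    vertices = directions * radius + center
    mesh = SurfaceMesh(structure_label, hemisphere, vertices, hull.simplices)
    fields = _harmonic_fields(directions, n_fields, rng)
    weights = rng.uniform(0.5, 1.5, size=n_fields) * rng.choice([-1, 1], size=n_fields)
    return SyntheticTemplate(structure_label, hemisphere, mesh, fields, weights)


@dataclass
class SyntheticSubject:
    """Latent trajectory of one simulated subject."""

    subject_id: str
    baseline_age: float
    group: str  # non_converter | MCI_converter | ADD_converter
    age_offset: float  # years of advanced structural age (0 for non-converters)
    aging_pace: float  # slope of effective age vs calendar time (1 for non-converters)
    scan_times: np.ndarray  # years from baseline
    shape_seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.aging_pace <= 0:
            raise ValueError("aging pace must be positive")
        if self.group == "non_converter" and (self.age_offset != 0 or self.aging_pace != 1):
            raise ValueError("non-converters must have offset 0 and pace 1")

    def effective_age(self, scan_time: float) -> float:
        return self.baseline_age + self.aging_pace * scan_time + self.age_offset


@dataclass
class CohortConfig:
    """Study conditions of a simulated cohort.

    Effect sizes default to amygdala-scale diagnosis offsets (+3.5 years
    MCI, +8 years ADD) and whole-brain-scale aging-pace multipliers (x1.12
    MCI, x1.31 ADD).  Shape deformation is affine in effective age with
    ``shape_gain`` units of displacement per field per year; an optional
    quadratic term bends the shape-age link to create the systematic
    prediction bias the correction stage must remove.
    """

    n_non_converters: int = 150
    n_mci_converters: int = 50
    n_add_converters: int = 50
    #: extra healthy subjects with a single acquisition — the pool the
    #: train/validation split draws from (repeated-scan subjects are
    #: reserved for testing)
    n_single_scan_healthy: int = 0
    scans_per_subject: int = 3
    follow_up_years: float = 4.0
    #: age range of the single-scan training/validation pool (wide, like the
    #: population cohorts networks are trained on)
    baseline_age_range: tuple[float, float] = (45.0, 95.0)
    #: baseline ages of the longitudinal groups (conversion cohorts are
    #: old-skewed, ~72 +/- 6, and must stay inside the training-age span so
    #: predictions are not extrapolations); None = same as baseline_age_range
    longitudinal_age_range: tuple[float, float] | None = (62.0, 82.0)
    #: converter age offsets at the longitudinal (pre-conversion) scale:
    #: subjects still healthy at baseline run only ~1-3 structural years
    #: ahead.  For cross-sectional studies of already-diagnosed patients
    #: configure larger offsets (~+3.5 MCI, ~+8 ADD) with
    #: ``baseline_diagnosed=True``.
    offset_mci: float = 1.2
    offset_add: float = 2.5
    pace_mci: float = 1.12
    pace_add: float = 1.31
    shape_gain: float = 0.03  # displacement units per year per field
    quadratic_gain: float = 0.0
    noise_sd: float = 0.5  # RMS vertex displacement of smooth shape noise
    structures: tuple[str, ...] = ("accumbens",)
    hemisphere: str = "L"
    switch_fraction: float = 0.5  # converters switch diagnosis at this follow-up fraction
    baseline_diagnosed: bool = False  # converters carry target diagnosis from baseline
    n_deformation_fields: int = 6
    age_center: float = 67.5  # effective age at which deformation vanishes
    seed: int = 0


def generate_scan_mesh(
    template: SyntheticTemplate,
    subject: SyntheticSubject,
    scan_time: float,
    noise_sd: float,
    rng: np.random.Generator,
    shape_gain: float = 0.03,
    quadratic_gain: float = 0.0,
    age_center: float = 67.5,
) -> SurfaceMesh:
    """Mesh of one scan: base + age-dependent deformation + smooth noise."""
    if scan_time < 0:
        raise ValueError("scan time must be >= 0")
    eff = subject.effective_age(scan_time)
    da = eff - age_center
    amps = shape_gain * template.field_weights * da
    if quadratic_gain:
        amps = amps + quadratic_gain * template.field_weights * (da**2) / 50.0
    disp = np.tensordot(amps, template.deformation_basis, axes=1)
    if noise_sd > 0:
        m = len(template.deformation_basis)
        eps = rng.normal(0.0, noise_sd / np.sqrt(m), size=m)
        disp = disp + np.tensordot(eps, template.deformation_basis, axes=1)
    return SurfaceMesh(
        template.structure_label,
        template.hemisphere,
        template.mesh.vertices + disp,
        template.mesh.faces,
    )


@dataclass
class SyntheticCohort:
    """Generated cohort: templates, subject trajectories, manifest, truth."""

    config: CohortConfig
    templates: dict[str, SyntheticTemplate]
    subjects: list[SyntheticSubject]
    manifest: pd.DataFrame  # subject_id, scan_id, age_at_scan, delta_scan, diagnosis
    truth: pd.DataFrame  # subject-level generating parameters

    def scan_mesh(self, subject: SyntheticSubject, scan_index: int, structure: str) -> SurfaceMesh:
        """Deterministically regenerate the mesh of one scan."""
        t = float(subject.scan_times[scan_index])
        rng = np.random.default_rng(
            np.random.SeedSequence([subject.shape_seed, scan_index])
        )
        return generate_scan_mesh(
            self.templates[structure],
            subject,
            t,
            self.config.noise_sd,
            rng,
            shape_gain=self.config.shape_gain,
            quadratic_gain=self.config.quadratic_gain,
            age_center=self.config.age_center,
        )

    def feature_dataset(self, structure: str) -> ScanDataset:
        """Per-scan input features for one structure, in manifest order."""
        feats, ages, sids, scids = [], [], [], []
        by_id = {s.subject_id: s for s in self.subjects}
        for row in self.manifest.itertuples():
            subj = by_id[row.subject_id]
            j = int(row.scan_index)
            mesh = self.scan_mesh(subj, j, structure)
            feats.append(build_features([mesh]))
            ages.append(row.age_at_scan)
            sids.append(row.subject_id)
            scids.append(row.scan_id)
        return ScanDataset(
            features=np.stack(feats),
            ages=np.array(ages),
            subject_ids=sids,
            scan_ids=scids,
        )


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Simulate a cohort under the given study conditions.

    Converters switch diagnosis at ``switch_fraction`` of the follow-up
    (or carry their target diagnosis from baseline if
    ``baseline_diagnosed``); scan times are evenly spread over the
    follow-up.  Identical config + seed reproduce the cohort byte for byte.
    """
    config = replace(config or CohortConfig(), **overrides)
    for s in config.structures:
        if s not in TEMPLATE_NODE_COUNTS:
            raise ValueError(f"unknown structure {s!r}")
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    templates = {
        s: make_template(
            s, config.hemisphere, seed=config.seed, n_fields=config.n_deformation_fields
        )
        for s in config.structures
    }
    counts = {
        "non_converter": config.n_non_converters,
        "MCI_converter": config.n_mci_converters,
        "ADD_converter": config.n_add_converters,
    }
    offsets = {"non_converter": 0.0, "MCI_converter": config.offset_mci, "ADD_converter": config.offset_add}
    paces = {"non_converter": 1.0, "MCI_converter": config.pace_mci, "ADD_converter": config.pace_add}
    if config.scans_per_subject > 1:
        times = np.linspace(0.0, config.follow_up_years, config.scans_per_subject)
    else:
        times = np.array([0.0])
    switch_at = config.switch_fraction * config.follow_up_years
    if config.baseline_diagnosed:
        switch_at = -1.0  # diagnosis holds from the first scan on

    subjects: list[SyntheticSubject] = []
    rows = []
    truth_rows = []
    k = 0
    plan = [(g, times) for g in GROUPS for _ in range(counts[g])]
    plan += [("non_converter", np.array([0.0]))] * config.n_single_scan_healthy
    long_range = config.longitudinal_age_range or config.baseline_age_range
    for group, subj_times in plan:
        sid = f"sub{k:05d}"
        age_range = config.baseline_age_range if len(subj_times) == 1 else long_range
        baseline = float(rng.uniform(*age_range))
        subj = SyntheticSubject(
            subject_id=sid,
            baseline_age=baseline,
            group=group,
            age_offset=offsets[group],
            aging_pace=paces[group],
            scan_times=subj_times.copy(),
            shape_seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(subj)
        for j, t in enumerate(subj_times):
            if group == "non_converter":
                diag = "healthy"
            else:
                diag = _GROUP_DIAGNOSIS[group] if t > switch_at else "healthy"
            rows.append(
                {
                    "subject_id": sid,
                    "scan_id": f"{sid}_s{j}",
                    "scan_index": j,
                    "age_at_scan": baseline + t,
                    "delta_scan": float(t),
                    "diagnosis": diag,
                }
            )
        truth_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "baseline_age": baseline,
                "age_offset": offsets[group],
                "aging_pace": paces[group],
                "shape_seed": subj.shape_seed,
            }
        )
        k += 1
    return SyntheticCohort(
        config=config,
        templates=templates,
        subjects=subjects,
        manifest=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, meshes: bool = True) -> Path:
    """Write manifest.csv, truth.csv and (optionally) per-scan PLY meshes.

    The cohort seed is recorded in a comment line at the top of each CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# structage synthetic cohort, seed={cohort.config.seed}\n"
    for name, df in (("manifest", cohort.manifest), ("truth", cohort.truth)):
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    if meshes:
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        by_id = {s.subject_id: s for s in cohort.subjects}
        for row in cohort.manifest.itertuples():
            subj = by_id[row.subject_id]
            for structure in cohort.config.structures:
                mesh = cohort.scan_mesh(subj, int(row.scan_index), structure)
                save_mesh(mesh, mesh_dir / f"{row.scan_id}_{structure}.ply")
    return out
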