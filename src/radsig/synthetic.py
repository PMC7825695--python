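"""Synthetic cohorts, pelvic phantoms, and feature tables.

The package analyses associations between MRI texture and medication usage
in a prostate-cancer cohort.  Patient images are never public, so every
downstream stage is exercised on synthetic data with the same statistical
structure:

* a cohort of patients with binary usage flags (statin, omega-3, ACEI)
  whose marginal and joint counts are controlled exactly;
* T2-weighted-like pelvic phantoms — an ellipsoidal gland containing a
  posterior-crescent peripheral zone — whose interior texture is a Gaussian
  random field whose mean, variance, and correlation length can shift with
  a binary label, degraded by a smooth multiplicative bias field and
  additive noise;
* patient-by-feature tables with a configurable number of informative
  columns (standardized mean difference between label groups) and blocks of
  correlated nuisance columns, mimicking the heavy redundancy of radiomic
  feature sets.

One master seed expands into per-patient substreams, so patient ``i`` is
identical no matter how many other patients are generated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import ImageVolume, ROIMask, read_mask, read_volume

__all__ = [
    "generate_cohort",
    "PhantomSpec",
    "PhantomEffect",
    "generate_phantom",
    "TableSpec",
    "SyntheticTable",
    "generate_feature_table",
    "write_dataset",
    "verify_manifest",
    "read_dataset_table",
]

DRUGS = ("statin", "omega3", "acei")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _as_count(value: float | int, n: int, what: str) -> int:
    """A prevalence given as a fraction in (0, 1) is converted to a count."""
    if isinstance(value, float) and 0 < value < 1:
        return int(round(value * n))
    count = int(value)
    if count < 0 or count > n:
        raise ValueError(f"{what} count {count} outside [0, {n}]")
    return count


def generate_cohort(
    n_patients: int,
    prevalences: dict[str, float | int],
    overlap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-patient binary medication flags with exact counts.

    Parameters
    ----------
    n_patients : int
        Cohort size.
    prevalences : dict
        Per-drug positive count (int) or fraction (float in (0,1)).
        Recognized drugs: ``statin``, ``omega3``, ``acei``; missing drugs
        default to zero users.
    overlap : int
        Number of patients using both statin and omega-3.  ACEI usage is
        assigned independently.
    seed : int
        Seed controlling which patients receive which flags.

    Returns
    -------
    DataFrame with columns ``patient_id, statin, omega3, acei`` and exactly
    the requested marginal and joint counts.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    unknown = set(prevalences) - set(DRUGS)
    if unknown:
        raise ValueError(f"unknown drugs {sorted(unknown)}; expected {DRUGS}")
    counts = {d: _as_count(prevalences.get(d, 0), n_patients, d) for d in DRUGS}
    overlap = int(overlap)
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if overlap > counts["statin"]:
        raise ValueError(
            f"overlap {overlap} exceeds statin count {counts['statin']}"
        )
    if overlap > counts["omega3"]:
        raise ValueError(
            f"overlap {overlap} exceeds omega3 count {counts['omega3']}"
        )
    n_any = counts["statin"] + counts["omega3"] - overlap
    if n_any > n_patients:
        raise ValueError(
            f"statin + omega3 - overlap = {n_any} exceeds cohort size {n_patients}"
        )

    rng = np.random.default_rng(seed)
    statin = np.zeros(n_patients, dtype=np.int64)
    omega3 = np.zeros(n_patients, dtype=np.int64)
    order = rng.permutation(n_patients)
    both = order[:overlap]
    statin_only = order[overlap : counts["statin"]]
    omega_only = order[counts["statin"] : n_any]
    statin[both] = statin[statin_only] = 1
    omega3[both] = omega3[omega_only] = 1

    acei = np.zeros(n_patients, dtype=np.int64)
    acei[rng.choice(n_patients, size=counts["acei"], replace=False)] = 1

    ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    return pd.DataFrame(
        {"patient_id": ids, "statin": statin, "omega3": omega3, "acei": acei}
    )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomEffect:
    """Label-dependent shifts of the gland texture parameters.

    ``mean_shift`` moves the mean interior intensity (intensity units),
    ``sd_scale`` multiplies the texture standard deviation, and
    ``corr_length_shift`` adds to the Gaussian-field correlation length
    (mm), so both first-order and texture statistics can carry signal.
    """

    mean_shift: float = 0.0
    sd_scale: float = 1.0
    corr_length_shift: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of a synthetic pelvic phantom.

    Defaults give a 64x64x32 grid at 1x1x2 mm (2 mm slice thickness, as in
    routine T2-weighted pelvic protocols) with an ellipsoidal gland and a
    posterior-crescent peripheral zone strictly inside it.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    gland_center: tuple[float, float, float] | None = None  # mm; None = grid center
    gland_radii: tuple[float, float, float] = (22.0, 18.0, 20.0)  # mm
    inner_fraction: float = 0.62  # inner ellipsoid scale delimiting the crescent
    base_intensity: float = 200.0
    background_intensity: float = 80.0
    texture_sd: float = 30.0
    corr_length: float = 4.0  # mm
    effect: PhantomEffect = field(default_factory=PhantomEffect)
    noise_sd: float = 10.0
    bias_amplitude: float = 0.2
    bias_length: float = 40.0  # mm; wavelength scale of the bias field
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 4 for s in self.shape):
            raise ValueError("phantom grid must be at least 4 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0 < self.inner_fraction < 1:
            raise ValueError("inner_fraction must be in (0, 1)")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be >= 0")


def _coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, radii) -> np.ndarray:
    q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
    return q <= 1.0


def phantom_masks(spec: PhantomSpec) -> tuple[ROIMask, ROIMask]:
    """Voxelize the gland ellipsoid and its posterior-crescent peripheral zone."""
    coords = _coords_mm(spec)
    center = spec.gland_center
    if center is None:
        center = tuple((n - 1) * s / 2 for n, s in zip(spec.shape, spec.spacing))
    gland = _ellipsoid(coords, center, spec.gland_radii)
    inner = _ellipsoid(
        coords, center, tuple(r * spec.inner_fraction for r in spec.gland_radii)
    )
    posterior = coords[1] > center[1]  # +y is posterior
    peripheral = gland & ~inner & posterior
    if not gland.any():
        raise ValueError("gland ROI is empty after voxelization")
    if not peripheral.any():
        raise ValueError("peripheral ROI is empty after voxelization")
    g = ROIMask(gland.astype(np.uint8), spec.spacing, name="prostate")
    p = ROIMask(peripheral.astype(np.uint8), spec.spacing, name="peripheral")
    return g, p


def _gaussian_random_field(
    rng: np.random.Generator, shape, spacing, corr_length: float
) -> np.ndarray:
    """Zero-mean unit-variance stationary field with Gaussian correlation."""
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return white
    sigma_vox = [corr_length / s for s in spacing]
    f = gaussian_filter(white, sigma_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(
    spec: PhantomSpec, label: int
) -> tuple[ImageVolume, ROIMask, ROIMask]:
    """Generate one phantom volume with its gland and peripheral masks.

    The interior texture is ``base + sd * GRF(corr_length)``; when
    ``label == 1`` the spec's :class:`PhantomEffect` shifts the mean, scales
    the standard deviation, and lengthens the field correlation inside the
    gland.  The volume is then multiplied by a smooth bias field
    ``1 + amplitude * smooth`` and degraded with additive Gaussian noise.
    Identical ``(spec, label)`` gives identical output.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    gland, peripheral = phantom_masks(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    eff = spec.effect
    mean = spec.base_intensity + (eff.mean_shift if label else 0.0)
    sd = spec.texture_sd * (eff.sd_scale if label else 1.0)
    corr = spec.corr_length + (eff.corr_length_shift if label else 0.0)

    # The same substream draws the texture for both labels so a zero effect
    # yields voxelwise-identical twins.
    texture = _gaussian_random_field(rng, spec.shape, spec.spacing, corr)
    interior = mean + sd * texture

    img = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    img[gland.voxels] = interior[gland.voxels]

    bias_raw = _gaussian_random_field(
        np.random.default_rng(np.random.SeedSequence((spec.seed, 1))),
        spec.shape,
        spec.spacing,
        spec.bias_length,
    )
    bias = 1.0 + spec.bias_amplitude * bias_raw / max(1e-12, np.abs(bias_raw).max())
    img *= bias

    noise_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    img += spec.noise_sd * noise_rng.standard_normal(spec.shape)

    return ImageVolume(img, spec.spacing), gland, peripheral


def cohort_phantom_spec(base: PhantomSpec, master_seed: int, patient_index: int) -> PhantomSpec:
    """Per-patient spec whose seed substream depends only on the patient index."""
    child = np.random.SeedSequence(master_seed).spawn(patient_index + 1)[patient_index]
    sub_seed = int(child.generate_state(1)[0] % (2**31))
    return PhantomSpec(**{**base.__dict__, "seed": sub_seed})


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSpec:
    """Parameters of a synthetic patient-by-feature table.

    ``effect`` is the standardized mean difference planted in the first
    ``n_informative`` columns; remaining columns are grouped in blocks of
    ``block_size`` sharing pairwise Pearson correlation ``block_r``.

    The defaults emulate a 91-patient, 944-feature radiomic table.  Real
    radiomic feature sets are massively redundant (near-duplicate features
    across classes and derived images), and the redundancy controls how
    optimistic whole-cohort feature selection can be on null labels; the
    default block structure (r = 0.95 in blocks of 40, ~24 effective
    factors) is calibrated so that a null-label analysis shows the same
    modest optimism that redundant real tables do.  Independent columns
    (``block_r=0``) overstate that optimism several-fold.
    """

    n_patients: int = 91
    n_features: int = 944
    n_informative: int = 6
    effect: float = 1.2
    block_r: float = 0.95
    block_size: int = 40
    prevalence: float | int = 42
    drug: str = "statin"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 <= n_informative <= n_features")
        if abs(self.block_r) > 1:
            raise ValueError("|block_r| must be <= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        n_pos = _as_count(self.prevalence, self.n_patients, "prevalence")
        if not 0 < n_pos < self.n_patients:
            raise ValueError("prevalence must leave both classes nonempty")
        if self.drug not in DRUGS:
            raise ValueError(f"drug must be one of {DRUGS}")


@dataclass(frozen=True)
class SyntheticTable:
    """A generated feature table, its cohort labels, and the planted truth."""

    features: pd.DataFrame  # index patient_id, columns feature names
    cohort: pd.DataFrame  # patient_id + drug flag columns
    informative: tuple[str, ...]  # names of the planted informative columns

    def labels(self, drug: str) -> pd.Series:
        return self.cohort.set_index("patient_id")[drug]


def _table_column_names(n: int) -> list[str]:
    """Radiomics-style column names; the real 944-name registry when it fits."""
    from .features.registry import all_feature_names

    registry = all_feature_names()
    if n <= len(registry):
        return registry[:n]
    extra = [f"synthetic_extra_f{i:04d}" for i in range(n - len(registry))]
    return registry + extra


def generate_feature_table(spec: TableSpec) -> SyntheticTable:
    """Generate a labelled table with planted effects and block correlation.

    Informative columns occupy distinct blocks of size 1 (so the planted
    signal is not duplicated by construction); nuisance columns are built
    from a shared-factor model ``sqrt(r) z_block + sqrt(1-r) e`` giving
    exact population correlation ``block_r`` within each block.
    """
    n, m = spec.n_patients, spec.n_features
    n_pos = _as_count(spec.prevalence, n, "prevalence")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    y = np.zeros(n, dtype=np.int64)
    y[rng.permutation(n)[:n_pos]] = 1

    X = np.empty((n, m), dtype=np.float64)
    k = spec.n_informative
    X[:, :k] = rng.standard_normal((n, k)) + spec.effect * y[:, None]

    n_noise = m - k
    if n_noise:
        r = spec.block_r
        if spec.block_size == 1 or r == 0:
            X[:, k:] = rng.standard_normal((n, n_noise))
        else:
            n_blocks = -(-n_noise // spec.block_size)
            z = rng.standard_normal((n, n_blocks))
            block_of = np.repeat(np.arange(n_blocks), spec.block_size)[:n_noise]
            e = rng.standard_normal((n, n_noise))
            sgn = np.sign(r)
            X[:, k:] = np.sqrt(abs(r)) * sgn * z[:, block_of] + np.sqrt(1 - abs(r)) * e

    names = _table_column_names(m)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    features = pd.DataFrame(X, index=pd.Index(ids, name="patient_id"), columns=names)

    cohort = pd.DataFrame({"patient_id": ids})
    for d in DRUGS:
        cohort[d] = y if d == spec.drug else 0
    return SyntheticTable(features, cohort, tuple(names[:k]))


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(
    cohort: pd.DataFrame,
    directory: str | Path,
    phantoms: list[tuple[str, ImageVolume, ROIMask, ROIMask]] | None = None,
    table: pd.DataFrame | None = None,
) -> dict:
    """Write a dataset directory and return its checksum manifest.

    ``phantoms`` is a list of ``(patient_id, volume, gland, peripheral)``;
    volumes/masks go to NIfTI, the cohort and feature table to CSV, and the
    manifest (also written as ``manifest.json``) lists every file with its
    SHA-256 checksum so corruption is detectable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    cohort_path = directory / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    files.append(cohort_path)

    if table is not None:
        table_path = directory / "features.csv"
        table.to_csv(table_path)
        files.append(table_path)

    for pid, vol, gland, peri in phantoms or []:
        for obj, suffix in ((vol, "image"), (gland, "mask-prostate"), (peri, "mask-peripheral")):
            p = directory / f"{pid}_{suffix}.nii.gz"
            obj.to_nifti(p)
            files.append(p)

    manifest = {
        "files": [
            {"name": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in files
        ]
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def verify_manifest(directory: str | Path) -> list[str]:
    """Re-hash every manifest entry; return the names that fail (empty = ok)."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    bad = []
    for entry in manifest["files"]:
        p = directory / entry["name"]
        if not p.exists() or _sha256(p) != entry["sha256"]:
            bad.append(entry["name"])
    return bad


def read_dataset_table(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back ``features.csv`` (indexed by patient) and ``cohort.csv``."""
    directory = Path(directory)
    table = pd.read_csv(directory / "features.csv", index_col="patient_id")
    cohort = pd.read_csv(directory / "cohort.csv")
    return table, cohort


def read_phantom(directory: str | Path, pid: str):
    """Read back one phantom written by :func:`write_dataset`."""
    directory = Path(directory)
    vol = read_volume(directory / f"{pid}_image.nii.gz")
    gland = read_mask(directory / f"{pid}_mask-prostate.nii.gz", name="prostate")
    peri = read_mask(directory / f"{pid}_mask-peripheral.nii.gz", name="peripheral")
    return vol, gland, peri
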