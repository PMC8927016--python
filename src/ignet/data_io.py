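"""Reading, validation, splitting and alignment of the four input artifacts.

Volumes are NIfTI-1 files carrying preprocessed T1 MRI at grayscale 0–255;
genotypes arrive as a VCF (GT field, diploid, biallelic) or a TSV dosage
matrix with values {0, 1, 2}; APOE e4 allele counts and diagnosis labels are
two-column TSV tables. A cohort is the inner join of all four on subject id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PARTITIONS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


# ---------------- volumes ----------------

@dataclass
class VolumeRecord:
    subject_id: str
    voxels: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"volume for {self.subject_id!r} has {self.voxels.ndim} axes, expected 3")
        if not np.isfinite(self.voxels).all():
            raise ValueError(f"non-finite intensities in volume {self.subject_id!r}")

    @property
    def dims(self) -> tuple:
        return self.voxels.shape


def read_volume(path, subject_id: str | None = None) -> VolumeRecord:
    """Load a 3D NIfTI-1 volume; intensities are returned unmodified."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    voxels = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if subject_id is None:
        name = str(path).rsplit("/", 1)[-1]
        subject_id = name.removesuffix(".gz").removesuffix(".nii")
    return VolumeRecord(subject_id=subject_id, voxels=voxels, voxel_size_mm=zooms)


def write_volume(record: VolumeRecord, path) -> None:
    affine = np.diag(list(record.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(record.voxels, affine), str(path))


def normalize_volume(record: VolumeRecord) -> VolumeRecord:
    """Map stored grayscale 0–255 to the network input scale [0, 1]."""
    v = np.asarray(record.voxels, dtype=np.float32)
    if v.min() < 0 or v.max() > 255:
        raise ValueError(
            f"intensities of {record.subject_id!r} outside [0, 255]: "
            f"range [{v.min()}, {v.max()}]")
    return VolumeRecord(subject_id=record.subject_id, voxels=v / 255.0,
                        voxel_size_mm=record.voxel_size_mm)


# ---------------- genotypes ----------------

@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage table; NaN marks a missing genotype."""

    dosages: pd.DataFrame

    def __post_init__(self):
        values = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = values[~ok].flat[0]
            raise ValueError(f"dosage value {bad!r} outside {{0,1,2}}/missing")
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicated subject ids in genotype matrix")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicated SNP ids in genotype matrix")

    @property
    def subject_ids(self):
        return list(self.dosages.index)

    @property
    def snp_ids(self):
        return list(self.dosages.columns)

    @property
    def n_missing(self) -> int:
        return int(self.dosages.isna().to_numpy().sum())


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (GT field) or a TSV dosage table.

    VCF genotypes are mapped to alternate-allele dosage: 0/0 -> 0, 0/1 or
    1/0 -> 1, 1/1 -> 2, ./. -> missing. Multi-allelic sites are rejected.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return GenotypeMatrix(dosages=df.astype(float))
    if format != "vcf":
        raise ValueError("format must be 'vcf' or 'tsv'")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic site {variant.CHROM}:{variant.POS} "
                f"({variant.ID or '.'}) is not supported")
        col = np.empty(len(subjects))
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            col[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    df = pd.DataFrame(np.column_stack(columns) if columns else np.empty((len(subjects), 0)),
                      index=pd.Index(subjects, name="subject_id"),
                      columns=snp_ids)
    return GenotypeMatrix(dosages=df)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    out = genotypes.dosages.copy()
    out.index.name = "subject_id"
    # integers where present, NA for missing
    out.to_csv(path, sep="\t", na_rep="NA",
               float_format=lambda x: f"{int(x)}" if float(x).is_integer() else str(x))


def impute_missing(genotypes: GenotypeMatrix, training_ids) -> GenotypeMatrix:
    """Fill missing dosages with the per-SNP mode among training subjects.

    Computing the mode on the training partition only keeps validation and
    test subjects out of every fitted quantity.
    """
    df = genotypes.dosages.copy()
    train = df.loc[df.index.intersection(pd.Index(training_ids))]
    for snp in df.columns[df.isna().any()]:
        counts = train[snp].value_counts()
        fill = float(counts.idxmax()) if len(counts) else 0.0
        df[snp] = df[snp].fillna(fill)
    return GenotypeMatrix(dosages=df)


# ---------------- tables ----------------

def read_apoe(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"subject_id", "apoe_e4_count"} <= set(df.columns):
        raise ValueError("APOE table needs columns subject_id, apoe_e4_count")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in APOE table")
    s = df.set_index("subject_id")["apoe_e4_count"].astype(int)
    if not s.isin([0, 1, 2]).all():
        raise ValueError("APOE e4 allele count must be in {0, 1, 2}")
    return s


def read_labels(path) -> pd.Series:
    """Diagnosis TSV (CN/AD) -> binary series (1 = AD) indexed by subject."""
    df = pd.read_csv(path, sep="\t")
    if not {"subject_id", "diagnosis"} <= set(df.columns):
        raise ValueError("label table needs columns subject_id, diagnosis")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in label table")
    if not df["diagnosis"].isin(["CN", "AD"]).all():
        raise ValueError("diagnosis must be 'CN' or 'AD'")
    return (df.set_index("subject_id")["diagnosis"] == "AD").astype(int)


# ---------------- splitting ----------------

def stratified_split(labels: pd.Series, fractions=DEFAULT_FRACTIONS,
                     seed: int = 0) -> pd.Series:
    """Assign each subject to train/val/test, stratified by class.

    Subjects of each class are shuffled with the given seed and allocated to
    partitions proportionally, with largest-remainder rounding, so every
    partition's class ratio tracks the cohort's. Deterministic per seed.
    """
    fractions = tuple(fractions)
    if len(fractions) != len(PARTITIONS) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    if labels.index.has_duplicates:
        raise ValueError("duplicated subject ids")
    rng = np.random.default_rng(seed)
    assignment = {}
    n = len(labels)
    global_quota = np.array([n * f for f in fractions])
    global_counts = np.zeros(len(PARTITIONS))
    for cls in sorted(labels.unique()):
        ids = np.array(sorted(labels.index[labels == cls]))
        rng.shuffle(ids)
        m = len(ids)
        quotas = np.array([m * f for f in fractions])
        counts = np.floor(quotas).astype(int)
        remainder = quotas - counts
        # leftover seats: largest remainder first, remainder ties broken by
        # the partition's global deficit so class roundings balance out
        deficit = global_quota - (global_counts + counts)
        order = np.lexsort((-deficit, -remainder))
        for k in order[: m - counts.sum()]:
            counts[k] += 1
        global_counts += counts
        bounds = np.cumsum(counts)
        for part, lo, hi in zip(PARTITIONS, np.r_[0, bounds[:-1]], bounds):
            for sid in ids[lo:hi]:
                assignment[sid] = part
    if (global_counts == 0).any():
        empty = [p for p, c in zip(PARTITIONS, global_counts) if c == 0]
        raise ValueError(f"cohort too small to populate partitions {empty}")
    out = pd.Series(assignment, name="partition")
    out.index.name = "subject_id"
    return out.loc[labels.index]


def write_split(split: pd.Series, path) -> None:
    split.rename("partition").to_frame().to_csv(path, sep="\t")


def read_split(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not df["partition"].isin(PARTITIONS).all():
        raise ValueError(f"partition must be one of {PARTITIONS}")
    return df.set_index("subject_id")["partition"]


# ---------------- cohort assembly ----------------

@dataclass
class Cohort:
    """Modality-aligned dataset, ordered by subject id."""

    subject_ids: list
    volumes: np.ndarray            # (N, D, H, W), normalized to [0, 1]
    genotypes: GenotypeMatrix      # aligned to subject_ids
    apoe: pd.Series                # e4 counts
    labels: pd.Series              # 1 = AD
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.subject_ids)


def assemble_cohort(volumes: dict, genotypes: GenotypeMatrix,
                    apoe: pd.Series, labels: pd.Series) -> Cohort:
    """Inner-join the four sources on subject id (sorted, deterministic).

    ``volumes`` maps subject id to a normalized VolumeRecord or a voxel
    array already scaled to [0, 1]. Subjects missing any modality are
    dropped; the drop count is logged and recorded on the cohort.
    """
    if labels.index.has_duplicates:
        raise ValueError("duplicated subject ids in labels")
    ids = (set(volumes) & set(genotypes.dosages.index)
           & set(apoe.index) & set(labels.index))
    if not ids:
        raise ValueError("no subject is present in all four sources")
    universe = (set(volumes) | set(genotypes.dosages.index)
                | set(apoe.index) | set(labels.index))
    n_dropped = len(universe) - len(ids)
    if n_dropped:
        log.info("dropped %d subjects missing at least one modality", n_dropped)
    order = sorted(ids)
    vols = []
    for sid in order:
        v = volumes[sid]
        vols.append(np.asarray(v.voxels if isinstance(v, VolumeRecord) else v,
                               dtype=np.float32))
    return Cohort(subject_ids=order,
                  volumes=np.stack(vols),
                  genotypes=GenotypeMatrix(dosages=genotypes.dosages.loc[order]),
                  apoe=apoe.loc[order],
                  labels=labels.loc[order],
                  n_dropped=n_dropped)


def build_sequences(cohort: Cohort, panel) -> np.ndarray:
    """Token matrix (N, panel length): panel dosages with APOE appended."""
    snps = [s for i, s in enumerate(panel.snp_ids)
            if panel.apoe_position is None or i != panel.apoe_position]
    tokens = cohort.genotypes.dosages[snps].to_numpy()
    if np.isnan(tokens).any():
        raise ValueError("missing dosages in panel SNPs; impute first")
    tokens = tokens.astype(np.int64)
    if panel.apoe_position is not None:
        e4 = cohort.apoe.to_numpy().astype(np.int64)[:, None]
        tokens = np.concatenate([tokens[:, :panel.apoe_position], e4,
                                 tokens[:, panel.apoe_position:]], axis=1)
    return tokens
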