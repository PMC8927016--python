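"""Synthetic imaging-genetics cohort generator.

Emulates the shape of the real study cohort — 379 subjects with a 174:205
AD:control ratio, {0,1,2} dosage-coded SNPs with one strong APOE-like locus
among many nulls, and 3D volumes whose class signal is a localized intensity
reduction — so that every stage of the pipeline is testable without access
to restricted data.

Genotypes follow Hardy–Weinberg equilibrium (dosage ~ Binomial(2, p) with
per-SNP allele frequency drawn uniformly from ``maf_range``). Disease status
comes from a logistic liability: a weighted sum of the causal dosages and
the APOE e4 count plus standard logistic noise, with the intercept solved by
bisection so the expected AD count matches the target. Volumes are a smooth
ellipsoidal "brain" phantom with additive Gaussian noise; a fixed cubic
region of interest has its intensity reduced in proportion to disease
liability and/or label (the ``coupling`` mixture), standing in for regional
atrophy. Voxel values are stored as 0–255 integers, as the volume readers
expect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, VolumeRecord, write_volume, write_genotypes_tsv


@dataclass
class SimConfig:
    n_subjects: int = 379
    n_ad_target: int = 174
    volume_dim: int = 32
    n_snps: int = 500
    n_causal: int = 5
    causal_log_odds: float = 0.5
    apoe_log_odds: float = 1.2
    apoe_maf: float = 0.2
    maf_range: tuple = (0.05, 0.5)
    roi_fraction: float = 0.1       # ROI cube side as a fraction of volume_dim
    atrophy_effect: float = 0.3     # fractional ROI intensity reduction in AD
    roi_between_sd: float = 0.15    # subject-level ROI brightness variability
    noise_sd: float = 0.1
    coupling: float = 0.5           # 1: liability-driven, 0: label-driven signal
    seed: int = 0

    def __post_init__(self):
        if not self.n_ad_target < self.n_subjects:
            raise ValueError("n_ad_target must be below n_subjects")
        if self.volume_dim % 32:
            raise ValueError("volume_dim must be divisible by 32")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf bounds must lie in (0, 0.5]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")


@dataclass
class SimulatedCohort:
    config: SimConfig
    subject_ids: list
    volumes: np.ndarray            # (N, d, d, d) uint8, grayscale 0-255
    genotypes: GenotypeMatrix
    apoe: pd.Series
    labels: pd.Series              # 1 = AD
    truth: dict                    # liabilities, causal SNPs, effect sizes, ROI


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """HWE genotypes plus an APOE-like locus; returns (matrix, apoe, causal idx)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_snps
    ids = [f"S{i:04d}" for i in range(n)]
    maf = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    snp_ids = [f"rs{j:06d}" for j in range(m)]
    matrix = GenotypeMatrix(dosages=pd.DataFrame(
        dosages, index=pd.Index(ids, name="subject_id"), columns=snp_ids))
    apoe = pd.Series(rng.binomial(2, config.apoe_maf, size=n),
                     index=matrix.dosages.index, name="apoe_e4_count")
    causal = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    return matrix, apoe, causal


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for b0 with sum sigmoid(b0 + eta) = target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + eta).sum() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _phantom(dim: int, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Smooth ellipsoidal brain phantom in [0, 1] with additive noise.

    The noise field is spatially correlated (white noise smoothed with a
    Gaussian kernel, rescaled to sd ``noise_sd``), emulating the smooth
    intensity inhomogeneity of preprocessed, down-sampled MRI rather than
    voxel-wise sensor noise.
    """
    from scipy.ndimage import gaussian_filter

    ax = (np.arange(dim) - (dim - 1) / 2) / (dim / 2)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    q = (x / 0.85) ** 2 + (y / 0.75) ** 2 + (z / 0.8) ** 2
    base = 0.05 + 0.70 * _sigmoid((1.0 - q) * 8.0)
    noise = gaussian_filter(rng.normal(0.0, 1.0, size=(dim, dim, dim)), sigma=1.5)
    noise *= noise_sd / max(noise.std(), 1e-12)
    return base + noise


def _roi_slices(config: SimConfig):
    dim = config.volume_dim
    side = max(1, round(config.roi_fraction * dim))
    if side > dim:
        raise ValueError("ROI larger than the volume")
    # fixed, slightly off-center location (a hippocampus-like target)
    center = (round(0.58 * dim), round(0.45 * dim), round(0.5 * dim))
    slices = tuple(slice(max(0, c - side // 2), max(0, c - side // 2) + side)
                   for c in center)
    return slices, side


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Full paired cohort: volumes + genotypes + APOE + labels + ground truth."""
    rng = np.random.default_rng(config.seed)
    genotypes, apoe, causal = simulate_genotypes(config, rng)
    dosage_arr = genotypes.dosages.to_numpy()
    betas = np.full(config.n_causal, config.causal_log_odds)
    eta = dosage_arr[:, causal] @ betas + config.apoe_log_odds * apoe.to_numpy()
    b0 = _solve_intercept(eta, config.n_ad_target)
    liability = b0 + eta + rng.logistic(size=config.n_subjects)
    labels = (liability > 0).astype(int)

    roi, side = _roi_slices(config)
    mix = (config.coupling * _sigmoid(b0 + eta)
           + (1.0 - config.coupling) * labels)
    # per-subject anatomical variability of ROI brightness, independent of
    # disease: gives the imaging channel a finite effect size
    roi_factor = ((1.0 - config.atrophy_effect * mix)
                  * (1.0 + rng.normal(0.0, config.roi_between_sd,
                                      size=config.n_subjects)))
    roi_factor = np.clip(roi_factor, 0.0, None)
    vols = np.empty((config.n_subjects,) + (config.volume_dim,) * 3, dtype=np.uint8)
    for i in range(config.n_subjects):
        v = _phantom(config.volume_dim, rng, config.noise_sd)
        v[roi] *= roi_factor[i]
        vols[i] = np.round(np.clip(v, 0.0, 1.0) * 255).astype(np.uint8)

    index = genotypes.dosages.index
    truth = {
        "liability": liability.tolist(),
        "intercept": b0,
        "causal_snp_ids": [genotypes.snp_ids[j] for j in causal],
        "causal_indices": causal.tolist(),
        "causal_log_odds": betas.tolist(),
        "apoe_log_odds": config.apoe_log_odds,
        "roi": [[s.start, s.stop] for s in roi],
    }
    return SimulatedCohort(
        config=config,
        subject_ids=list(index),
        volumes=vols,
        genotypes=genotypes,
        apoe=apoe,
        labels=pd.Series(labels, index=index, name="label"),
        truth=truth)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict:
    """Emit the cohort in exactly the formats the readers consume.

    Writes one NIfTI per subject, the genotype/APOE/label TSVs, the ground
    truth JSON, and a manifest of file content hashes; returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol_dir = out / "volumes"
    vol_dir.mkdir(exist_ok=True)
    files = []
    for i, sid in enumerate(cohort.subject_ids):
        path = vol_dir / f"{sid}.nii.gz"
        write_volume(VolumeRecord(subject_id=sid,
                                  voxels=cohort.volumes[i]), path)
        files.append(path)

    write_genotypes_tsv(cohort.genotypes, out / "genotypes.tsv")
    cohort.apoe.rename("apoe_e4_count").to_frame().to_csv(
        out / "apoe.tsv", sep="\t")
    diag = cohort.labels.map({0: "CN", 1: "AD"}).rename("diagnosis")
    diag.to_frame().to_csv(out / "labels.tsv", sep="\t")
    (out / "truth.json").write_text(
        json.dumps({"config": asdict(cohort.config), **cohort.truth}, indent=1))
    files += [out / "genotypes.tsv", out / "apoe.tsv",
              out / "labels.tsv", out / "truth.json"]

    manifest = {str(p.relative_to(out)): _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
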