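"""Synthetic cortical-thickness cohorts for exercising the SCN pipeline.

Real structural-correlation-network studies start from per-subject regional
cortical thickness (mm) estimated from T1 MRI.  This module generates
cohorts with the statistical features that the downstream analysis relies
on: group-specific inter-regional correlation structure organised into
modules, strong homotopic (left-right counterpart) correlations, and
additive age / gender / age-by-gender effects on thickness.

The default configuration emulates the study conditions the pipeline is
designed for: 49 subjects split 16 Val homozygotes / 33 Met carriers
(BDNF Val66Met genotype counts 16/28/5), 68 Desikan-Killiany regions,
age 41.1 +/- 11.3 years in [20, 65], and 36:13 male:female.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .regions import default_module_partition, default_region_labels, homotopic_pairs

VAL_HOMOZYGOTE = "ValHomozygote"
MET_CARRIER = "MetCarrier"
GROUPS = (VAL_HOMOZYGOTE, MET_CARRIER)
GENOTYPES = ("Val/Val", "Val/Met", "Met/Met")


def group_of_genotype(genotype: str) -> str:
    """Group assignment rule: carriers of at least one Met allele form one group."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    return VAL_HOMOZYGOTE if genotype == "Val/Val" else MET_CARRIER


@dataclass
class CohortConfig:
    """Parameters of the synthetic-cohort generator.

    ``r_within``, ``r_between`` and ``r_homotopic`` are per-group target
    correlations of the region-level residual noise (after covariate
    effects); keys are group names.  ``covariate_betas`` holds the age
    slope (mm/year), gender offset (mm, male minus female) and
    age-by-gender interaction (mm/year).
    """

    n_subjects_per_group: tuple[int, int] = (16, 33)  # (Val homozygotes, Met carriers)
    n_regions: int = 68
    region_labels: list[str] | None = None
    age_mean: float = 41.1
    age_sd: float = 11.3
    age_range: tuple[float, float] = (20.0, 65.0)
    male_fraction: float = 36 / 49
    genotype_probs: tuple[float, float, float] = (16 / 49, 28 / 49, 5 / 49)
    module_partition: dict[str, int] | None = None
    r_within: dict[str, float] = field(
        default_factory=lambda: {VAL_HOMOZYGOTE: 0.40, MET_CARRIER: 0.60}
    )
    r_between: dict[str, float] = field(
        default_factory=lambda: {VAL_HOMOZYGOTE: 0.15, MET_CARRIER: 0.15}
    )
    r_homotopic: dict[str, float] = field(
        default_factory=lambda: {VAL_HOMOZYGOTE: 0.70, MET_CARRIER: 0.75}
    )
    baseline_thickness: float = 2.8  # mm, typical mean DK regional thickness
    covariate_betas: tuple[float, float, float] = (-0.008, -0.03, 0.0)
    noise_sd: float = 0.12  # mm
    genotype_sampling: str = "apportion"  # or "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_labels is None:
            self.region_labels = default_region_labels(self.n_regions)
        if self.module_partition is None:
            self.module_partition = default_module_partition(self.region_labels)
        self.validate()

    def validate(self) -> None:
        n_val, n_met = self.n_subjects_per_group
        if n_val <= 0 or n_met <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_regions % 2 != 0 or self.n_regions < 2:
            raise ValueError("n_regions must be a positive even integer")
        if len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length must equal n_regions")
        if len(set(self.region_labels)) != self.n_regions:
            raise ValueError("region_labels must be unique")
        if abs(sum(self.genotype_probs) - 1.0) > 1e-12:
            raise ValueError("genotype_probs must sum to 1")
        if any(p < 0 for p in self.genotype_probs):
            raise ValueError("genotype_probs must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 < self.male_fraction < 1.0):
            raise ValueError("male_fraction must be in (0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be a non-empty interval")
        if self.genotype_sampling not in ("apportion", "multinomial"):
            raise ValueError("genotype_sampling must be 'apportion' or 'multinomial'")
        for g in GROUPS:
            rw, rb, rh = self.r_within[g], self.r_between[g], self.r_homotopic[g]
            if not (0.0 <= rb <= rw < 1.0):
                raise ValueError(
                    f"{g}: need 0 <= r_between <= r_within < 1, got {rb}, {rw}"
                )
            if not (0.0 <= rh < 1.0):
                raise ValueError(f"{g}: r_homotopic must be in [0, 1)")
        missing = [lab for lab in self.region_labels if lab not in self.module_partition]
        if missing:
            raise ValueError(f"module_partition missing regions: {missing[:3]}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """A generated (or loaded) cohort: covariates joined to thickness.

    ``table`` is indexed by subject id with columns ``group``, ``genotype``,
    ``age``, ``gender`` followed by one column per region label.
    """

    table: pd.DataFrame
    region_labels: list[str]

    COVARIATE_COLS = ("group", "genotype", "age", "gender")

    @property
    def thickness(self) -> pd.DataFrame:
        return self.table[self.region_labels]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table[list(self.COVARIATE_COLS)]

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.table["group"] == group).to_numpy()

    def validate(self) -> None:
        for col in self.COVARIATE_COLS:
            if col not in self.table.columns:
                raise ValueError(f"cohort table missing covariate column {col!r}")
        bad = [
            g for g in self.table["genotype"] if g not in GENOTYPES
        ]
        if bad:
            raise ValueError(f"unknown genotypes: {sorted(set(bad))}")
        expected = self.table["genotype"].map(group_of_genotype)
        if not (expected == self.table["group"]).all():
            raise ValueError("group labels inconsistent with Met-allele grouping rule")
        thick = self.thickness.to_numpy(float)
        if not np.all(thick > 0):
            raise ValueError("thickness values must be strictly positive")


def nearest_positive_definite_correlation(
    mat: np.ndarray, min_eig: float = 1e-8, max_iter: int = 20
) -> np.ndarray:
    """Repair a symmetric matrix to the nearest well-conditioned correlation matrix.

    Eigenvalue clipping followed by diagonal renormalisation, iterated until
    the smallest eigenvalue is at least ``min_eig``.
    """
    a = (mat + mat.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(a)
        if vals[0] >= min_eig:
            np.fill_diagonal(a, 1.0)
            return a
        vals = np.clip(vals, min_eig, None)
        a = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
    vals = np.linalg.eigvalsh(a)
    if vals[0] < min_eig:
        raise ValueError(
            f"correlation repair failed: smallest eigenvalue {vals[0]:.3e} < {min_eig}"
        )
    return a


def build_group_correlation(config: CohortConfig, group: str) -> np.ndarray:
    """Target residual correlation matrix for one group.

    Entries: ``r_within`` inside modules, ``r_between`` across modules and
    ``r_homotopic`` on left-right counterpart pairs, unit diagonal; repaired
    to positive definite if necessary.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    n = config.n_regions
    part = np.array([config.module_partition[lab] for lab in config.region_labels])
    same_module = part[:, None] == part[None, :]
    corr = np.where(same_module, config.r_within[group], config.r_between[group])
    corr = corr.astype(float)
    for i, j in homotopic_pairs(n):
        corr[i, j] = corr[j, i] = config.r_homotopic[group]
    np.fill_diagonal(corr, 1.0)
    return nearest_positive_definite_correlation(corr)


def _apportion(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n items to probabilities."""
    quota = probs * n
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return counts


def _draw_ages(rng: np.random.Generator, n: int, config: CohortConfig) -> np.ndarray:
    """Truncated-normal ages by rejection sampling."""
    lo, hi = config.age_range
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(config.age_mean, config.age_sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        ages[filled : filled + take] = keep[:take]
        filled += take
    return ages


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort.

    Genotypes determine groups via the Met-allele rule; thickness is
    baseline + covariate effects + multivariate-normal residual noise with
    the group's target correlation matrix scaled by ``noise_sd``.
    Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_val, n_met = config.n_subjects_per_group
    n = n_val + n_met
    probs = np.asarray(config.genotype_probs, float)

    if config.genotype_sampling == "apportion":
        counts = _apportion(probs, n)
    else:
        counts = rng.multinomial(n, probs)
    genotypes = np.repeat(np.array(GENOTYPES, dtype=object), counts)
    rng.shuffle(genotypes)
    groups = np.array([group_of_genotype(g) for g in genotypes], dtype=object)
    sizes = {g: int((groups == g).sum()) for g in GROUPS}
    if min(sizes.values()) == 0:
        raise ValueError(f"degenerate cohort: a group is empty ({sizes})")

    ages = _draw_ages(rng, n, config)
    male = rng.random(n) < config.male_fraction
    gender = np.where(male, "M", "F")

    beta_age, beta_gender, beta_inter = config.covariate_betas
    base = (
        config.baseline_thickness
        + beta_age * ages
        + beta_gender * male.astype(float)
        + beta_inter * ages * male.astype(float)
    )

    thickness = np.empty((n, config.n_regions))
    for g in GROUPS:
        mask = groups == g
        corr = build_group_correlation(config, g)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((mask.sum(), config.n_regions))
        resid = config.noise_sd * (z @ chol.T)
        thickness[mask] = base[mask, None] + resid

    subject_ids = [f"sub{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "group": groups,
            "genotype": genotypes,
            "age": ages,
            "gender": gender,
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    table = pd.concat(
        [table, pd.DataFrame(thickness, index=table.index, columns=config.region_labels)],
        axis=1,
    )
    cohort = Cohort(table=table, region_labels=list(config.region_labels))
    cohort.validate()
    return cohort
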