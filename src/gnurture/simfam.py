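"""Synthetic family genotype + phenotype generator with known ground truth.

Families of genotyped parent-offspring trios and single-genotyped-parent pairs
are simulated forward in time: founder haplotypes are drawn from per-marker
allele frequencies (no background LD by default), mates are paired with an
optional genetic assortment knob, gametes are produced under the Haldane
recombination model on a genetic map, and phenotypes follow a causal structure
with a direct genetic path from the offspring's own score and a nurture path
from each parent's phenotype.  Every meiosis records per-marker transmission
truth, so downstream inference can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

MISSING = np.int8(-1)

__all__ = [
    "GeneticMap",
    "HaplotypeSet",
    "TransmissionTruth",
    "PhenoModelParams",
    "SyntheticDataset",
    "build_genetic_map",
    "simulate_founders",
    "pair_mates",
    "meiosis",
    "build_families",
    "simulate_phenotypes",
    "add_switch_errors",
    "simulate_dataset",
    "simulate_analysis_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: one row per marker, ordered by (chromosome, local index).

    ``table`` columns: marker_id, chrom, local_index, cm, pos (1-based bp).
    Genetic positions are non-decreasing within a chromosome and marker ids
    are unique genome-wide.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["marker_id"].duplicated().any():
            raise ValueError("marker ids must be unique genome-wide")
        for _, sub in t.groupby("chrom", sort=False):
            if (np.diff(sub["cm"].to_numpy()) < 0).any():
                raise ValueError("genetic positions must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_cm(self, chrom) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "cm"].to_numpy(float)

    def chrom_length_cm(self, chrom) -> float:
        cm = self.chrom_cm(chrom)
        return float(cm[-1]) if len(cm) else 0.0


@dataclass
class HaplotypeSet:
    """Phased haplotypes: individual id -> (2, n_markers) array of 0/1 codes.

    Code -1 marks a missing allele.  Genotype dosage is hap1 + hap2.
    """

    gmap: GeneticMap
    haps: dict = field(default_factory=dict)

    def individuals(self) -> list:
        return list(self.haps)

    def dosage(self, ind: str) -> np.ndarray:
        h = self.haps[ind]
        d = h[0].astype(np.int16) + h[1]
        d[(h[0] < 0) | (h[1] < 0)] = -1
        return d

    def copy(self) -> "HaplotypeSet":
        return HaplotypeSet(self.gmap, {k: v.copy() for k, v in self.haps.items()})


@dataclass
class TransmissionTruth:
    """Ground-truth transmission per offspring meiosis.

    ``source[offspring][role]``: (n_markers,) array in {1, 2} — which parental
    haplotype each transmitted allele came from.  ``crossovers`` holds the cM
    positions of each recombination event per chromosome.
    """

    source: dict = field(default_factory=dict)
    crossovers: dict = field(default_factory=dict)


@dataclass
class PhenoModelParams:
    """Structural parameters of the phenotype model (all effects per SD).

    Parent phenotype:  P = gamma * Z(G_parent) + e_p.
    Offspring latent:  L = delta * Z(G_off) + eta_m * Z(P_m) + eta_f * Z(P_f)
                         + nurture_direct * (Z(G_m) + Z(G_f))
                         + beta_sex * sex + beta_age * Z(age) + eps.
    Binary traits threshold a latent liability at the target prevalence;
    quantity traits are observed only in initiators.  ``nurture_direct`` is a
    residual nurture path that bypasses the parental-phenotype mediator, so
    mediation is partial by default.
    """

    delta: float = 0.18
    eta_m: float = 0.12
    eta_f: float = 0.12
    gamma: float = 0.40
    rho_am: float = 0.0
    nurture_direct: float = 0.03
    beta_sex: float = 0.10
    beta_age: float = 0.05
    resid_sd: float = 1.0
    parent_resid_sd: float = 1.0
    prev_smoking_init: float = 0.414
    prev_cannabis: float = 0.227
    cannabis_measured_frac: float = 0.57
    parent_pheno_missing: dict = field(
        default_factory=lambda: {"mother": 0.15, "father": 0.40}
    )
    age_range: tuple = (18.0, 67.0)

    def validate(self) -> None:
        if not (0.0 <= self.rho_am <= 1.0):
            raise ValueError("rho_AM must be in [0, 1]")
        for p in (self.prev_smoking_init, self.prev_cannabis):
            if not (0.0 < p < 1.0):
                raise ValueError("prevalences must be in (0, 1)")
        if self.resid_sd <= 0 or self.parent_resid_sd <= 0:
            raise ValueError("residual SDs must be positive")


@dataclass
class SyntheticDataset:
    """Bundle of everything a pipeline run consumes, with ground truth."""

    gmap: GeneticMap
    haps: HaplotypeSet            # what the pipeline sees (may carry switch errors)
    truth_haps: HaplotypeSet      # error-free phase, for concordance vs truth
    pedigree: pd.DataFrame
    truth: TransmissionTruth
    phenotypes: pd.DataFrame
    weights: pd.DataFrame
    freqs: np.ndarray
    pcs: pd.DataFrame | None = None
    batches: pd.Series | None = None
    params: PhenoModelParams | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_genetic_map(
    n_chromosomes: int, markers_per_chromosome: int, length_cm: float
) -> GeneticMap:
    """Evenly spaced markers on [0, length_cm] per chromosome, deterministic."""
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("chromosome and marker counts must be >= 1")
    if length_cm < 0:
        raise ValueError("map length must be non-negative")
    rows = []
    for c in range(1, n_chromosomes + 1):
        if markers_per_chromosome == 1:
            cm = np.array([0.0])
        else:
            cm = np.linspace(0.0, length_cm, markers_per_chromosome)
        for i in range(markers_per_chromosome):
            rows.append(
                (f"c{c}_m{i}", c, i, float(cm[i]), 10_000 * (i + 1))
            )
    table = pd.DataFrame(rows, columns=["marker_id", "chrom", "local_index", "cm", "pos"])
    return GeneticMap(table)


def simulate_founders(
    n: int, freqs: np.ndarray, gmap: GeneticMap, seed: int, prefix: str = "ind"
) -> HaplotypeSet:
    """Draw ``n`` founders; each haplotype allele is Bernoulli(freq) per marker."""
    freqs = np.asarray(freqs, float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(freqs) != gmap.n_markers:
        raise ValueError("frequency panel length must match the map")
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele frequencies must lie in the open interval (0, 1)")
    rng = substream(seed, "founders") if isinstance(seed, int) else seed
    haps = {}
    for i in range(n):
        draw = (rng.random((2, gmap.n_markers)) < freqs).astype(np.int8)
        haps[f"{prefix}{i}"] = draw
    return HaplotypeSet(gmap, haps)


def pair_mates(
    mother_scores: np.ndarray,
    father_scores: np.ndarray,
    rho_am: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pair mothers to fathers with target mate-score correlation ``rho_am``.

    Rank interleaving with Gaussian noise: each pool is sorted on a noisy key
    k = sqrt(rho) * z(score) + sqrt(1 - rho) * eps and matched by rank, which
    yields a realized mate correlation of approximately rho for large pools
    (rho = 0 gives random pairing, rho = 1 perfect rank matching).

    Returns ``pairing`` such that mother i mates with father ``pairing[i]``.
    """
    mother_scores = np.asarray(mother_scores, float)
    father_scores = np.asarray(father_scores, float)
    if len(mother_scores) != len(father_scores):
        raise ValueError("mother and father pools must have equal size")
    if not (0.0 <= rho_am <= 1.0):
        raise ValueError("rho_AM must be in [0, 1]")
    n = len(mother_scores)

    def _z(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    lam = np.sqrt(rho_am)
    noise = np.sqrt(1.0 - rho_am)
    km = lam * _z(mother_scores) + noise * rng.standard_normal(n)
    kf = lam * _z(father_scores) + noise * rng.standard_normal(n)
    pairing = np.empty(n, dtype=int)
    pairing[np.argsort(km, kind="stable")] = np.argsort(kf, kind="stable")
    return pairing


def meiosis(
    parent_haps: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
):
    """One meiosis under the Haldane model (Poisson crossovers, no interference).

    Returns ``(gamete, source, crossovers)`` where ``source`` is the per-marker
    parental haplotype index in {1, 2} and ``crossovers`` maps chromosome ->
    sorted cM positions of recombination events.
    """
    M = gmap.n_markers
    if parent_haps.shape != (2, M):
        raise ValueError("parental haplotypes must match the map")
    source = np.empty(M, dtype=np.int8)
    crossovers = {}
    for chrom in gmap.chroms:
        sl = gmap.chrom_slice(chrom)
        cm = gmap.table["cm"].to_numpy(float)[sl]
        length = cm[-1] if len(cm) else 0.0
        n_cx = rng.poisson(length / 100.0)
        pos = np.sort(rng.uniform(0.0, length, n_cx)) if n_cx else np.empty(0)
        start = int(rng.integers(2))
        flips = np.searchsorted(pos, cm, side="left")
        source[sl] = ((start + flips) % 2 + 1).astype(np.int8)
        crossovers[chrom] = pos
    gamete = parent_haps[source - 1, np.arange(M)]
    return gamete, source, crossovers


def build_families(
    parents: HaplotypeSet,
    couples: list,
    n_offspring_per_couple,
    pair_fraction: float,
    father_masked_share: float,
    rng: np.random.Generator,
):
    """Mate couples, produce offspring via meiosis, and record truth.

    ``couples`` is a list of (mother_id, father_id).  ``n_offspring_per_couple``
    is an int or an inclusive (lo, hi) range sampled uniformly per family.  In a
    ``pair_fraction`` share of families one parent's genotyped flag is cleared
    (the father with probability ``father_masked_share``).

    Returns (pedigree DataFrame, HaplotypeSet incl. offspring, TransmissionTruth).
    """
    if not (0.0 <= pair_fraction <= 1.0):
        raise ValueError("pair_fraction must be in [0, 1]")
    gmap = parents.gmap
    haps = parents.copy()
    truth = TransmissionTruth()
    rows = []
    for fam_idx, (mid, fid) in enumerate(couples):
        fam = f"fam{fam_idx:05d}"
        is_pair = rng.random() < pair_fraction
        mask_father = rng.random() < father_masked_share
        m_geno = not (is_pair and not mask_father)
        f_geno = not (is_pair and mask_father)
        rows.append((fam, mid, "mother", m_geno, True))
        rows.append((fam, fid, "father", f_geno, True))
        if isinstance(n_offspring_per_couple, int):
            n_off = n_offspring_per_couple
        else:
            lo, hi = n_offspring_per_couple
            n_off = int(rng.integers(lo, hi + 1))
        for k in range(n_off):
            oid = f"{fam}_o{k}"
            g_m, src_m, cx_m = meiosis(haps.haps[mid], gmap, rng)
            g_f, src_f, cx_f = meiosis(haps.haps[fid], gmap, rng)
            haps.haps[oid] = np.stack([g_m, g_f]).astype(np.int8)
            truth.source[oid] = {"mother": src_m, "father": src_f}
            truth.crossovers[oid] = {"mother": cx_m, "father": cx_f}
            rows.append((fam, oid, "offspring", True, True))
    pedigree = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "role", "genotyped", "phenotyped"]
    )
    return pedigree, haps, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    s = np.nanstd(x)
    return (x - np.nanmean(x)) / s if s > 0 else np.zeros_like(x)


def true_scores(haps: HaplotypeSet, weights: pd.DataFrame) -> pd.Series:
    """Weight-based true score per individual: sum_j w_j * dosage_j."""
    w = weights["weight"].to_numpy(float)
    ids = haps.individuals()
    vals = [float(np.dot(w, haps.dosage(i))) for i in ids]
    return pd.Series(vals, index=ids, dtype=float)


def _liability_binary(latent: np.ndarray, prevalence: float) -> np.ndarray:
    """Threshold a latent liability at the quantile matching target prevalence."""
    z = _zscore(latent)
    from scipy.stats import norm

    thr = norm.ppf(1.0 - prevalence)
    return (z > thr).astype(float)


def simulate_phenotypes(
    pedigree: pd.DataFrame,
    haps: HaplotypeSet,
    weights: pd.DataFrame,
    params: PhenoModelParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate parent and offspring phenotypes under the structural model.

    Emits one row per offspring with its own outcomes (smk_init, cig_day,
    pack_years, alc_gday, cannabis_ever), covariates (sex: 1 = female, age),
    the parental mediator candidates (mother_cig_day, mother_pack_years,
    father_cig_day, father_pack_years) and the latent truth columns
    (``true_*``) used by oracle tests.  Quantity outcomes are missing for
    non-initiators; parental phenotypes are missing at the configured rates;
    cannabis is measured only in a subset (a later assessment wave analogue).
    """
    params.validate()
    need = set(weights["marker_id"])
    have = set(haps.gmap.table["marker_id"])
    if not need.issubset(have):
        raise ValueError("weights must cover markers present in the map")

    g = true_scores(haps, weights)
    ped = pedigree.set_index("individual_id")
    offspring = ped[ped["role"] == "offspring"]
    mothers = ped[ped["role"] == "mother"]
    fathers = ped[ped["role"] == "father"]
    fam_mother = {f: i for i, f in mothers["family_id"].items()}
    fam_father = {f: i for i, f in fathers["family_id"].items()}

    # parent generation: phenotype P = gamma * Z(G) + e
    parent_ids = list(mothers.index) + list(fathers.index)
    zg_parent = pd.Series(_zscore(g.loc[parent_ids].to_numpy()), index=parent_ids)

    def parent_pheno():
        e = rng.normal(0.0, params.parent_resid_sd, len(parent_ids))
        return pd.Series(
            params.gamma * zg_parent.to_numpy() + e, index=parent_ids
        )

    p_cig = parent_pheno()
    p_py = parent_pheno()

    off_ids = list(offspring.index)
    n = len(off_ids)
    zg_off = _zscore(g.loc[off_ids].to_numpy())
    fam = offspring["family_id"].to_numpy()
    mid = np.array([fam_mother[f] for f in fam])
    fid = np.array([fam_father[f] for f in fam])

    sex = (rng.random(n) < 0.5).astype(float)
    age = rng.uniform(*params.age_range, n)
    zage = _zscore(age)

    zp_m_cig = _zscore(p_cig.loc[mid].to_numpy())
    zp_f_cig = _zscore(p_cig.loc[fid].to_numpy())
    zp_m_py = _zscore(p_py.loc[mid].to_numpy())
    zp_f_py = _zscore(p_py.loc[fid].to_numpy())
    zg_m = _zscore(g.loc[mid].to_numpy())
    zg_f = _zscore(g.loc[fid].to_numpy())

    def latent(zp_m, zp_f):
        return (
            params.delta * zg_off
            + params.eta_m * zp_m
            + params.eta_f * zp_f
            + params.nurture_direct * (zg_m + zg_f)
            + params.beta_sex * sex
            + params.beta_age * zage
            + rng.normal(0.0, params.resid_sd, n)
        )

    smk_init = _liability_binary(latent(zp_m_cig, zp_f_cig), params.prev_smoking_init)
    cig_day = 10.24 + 6.0 * latent(zp_m_cig, zp_f_cig)
    pack_years = 7.03 + 6.7 * latent(zp_m_py, zp_f_py)
    alc_gday = 6.74 + 8.5 * latent(zp_m_cig, zp_f_cig)
    cannabis = _liability_binary(latent(zp_m_cig, zp_f_cig), params.prev_cannabis)

    init = smk_init > 0
    cig_day = np.where(init, cig_day, np.nan)
    pack_years = np.where(init, pack_years, np.nan)
    cannabis = np.where(rng.random(n) < params.cannabis_measured_frac, cannabis, np.nan)

    def parent_col(vals, roles_missing_rate):
        out = vals.copy()
        miss = rng.random(n) < roles_missing_rate
        out[miss] = np.nan
        return out

    mr = params.parent_pheno_missing.get("mother", 0.0)
    fr = params.parent_pheno_missing.get("father", 0.0)
    pheno = pd.DataFrame(
        {
            "individual_id": off_ids,
            "family_id": fam,
            "sex": sex,
            "age": age,
            "smk_init": smk_init,
            "cig_day": cig_day,
            "pack_years": pack_years,
            "alc_gday": alc_gday,
            "cannabis_ever": cannabis,
            "mother_cig_day": parent_col(10.24 + 6.0 * zp_m_cig, mr),
            "father_cig_day": parent_col(10.24 + 6.0 * zp_f_cig, fr),
            "mother_pack_years": parent_col(7.03 + 6.7 * zp_m_py, mr),
            "father_pack_years": parent_col(7.03 + 6.7 * zp_f_py, fr),
            "true_g_z": zg_off,
            "true_g_mother_z": zg_m,
            "true_g_father_z": zg_f,
            "true_p_mother_z": zp_m_cig,
            "true_p_father_z": zp_f_cig,
        }
    )
    return pheno


def add_switch_errors(
    haps: HaplotypeSet, rate: float, rng: np.random.Generator
) -> HaplotypeSet:
    """Introduce phase-switch errors: at each marker, with probability ``rate``,
    swap the remaining suffix of the individual's two haplotypes.  Dosages are
    unchanged by construction."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("switch-error rate must be in [0, 1)")
    out = haps.copy()
    if rate == 0.0:
        return out
    M = haps.gmap.n_markers
    for ind, h in out.haps.items():
        switch = rng.random(M) < rate
        parity = np.cumsum(switch) % 2 == 1
        swapped = h[::-1].copy()
        h[:, parity] = swapped[:, parity]
    return out


# ---------------------------------------------------------------------------
# convenience drivers
# ---------------------------------------------------------------------------


def simulate_dataset(
    n_families: int = 300,
    n_chromosomes: int = 2,
    markers_per_chromosome: int = 3000,
    length_cm: float = 100.0,
    freq_range: tuple = (0.05, 0.95),
    params: PhenoModelParams | None = None,
    n_offspring_per_couple=(1, 3),
    pair_fraction: float = 0.83,
    father_masked_share: float = 0.7,
    switch_error_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a complete synthetic study: map, families, truth, phenotypes,
    SNP weights.  All randomness flows from named substreams of ``seed``, so a
    fixed seed yields a byte-identical dataset."""
    params = params or PhenoModelParams()
    gmap = build_genetic_map(n_chromosomes, markers_per_chromosome, length_cm)
    freq_rng = substream(seed, "freqs")
    freqs = freq_rng.uniform(*freq_range, gmap.n_markers)

    founders = simulate_founders(2 * n_families, freqs, gmap, seed)
    ids = founders.individuals()
    mother_ids = ids[:n_families]
    father_ids = ids[n_families:]

    w_rng = substream(seed, "weights")
    weights = pd.DataFrame(
        {
            "marker_id": gmap.table["marker_id"],
            "chrom": gmap.table["chrom"],
            "pos": gmap.table["pos"],
            "effect_allele": "B",
            "other_allele": "A",
            "weight": w_rng.normal(0.0, 1.0, gmap.n_markers)
            / np.sqrt(gmap.n_markers),
        }
    )

    g = true_scores(founders, weights)
    mate_rng = substream(seed, "mating")
    pairing = pair_mates(
        g.loc[mother_ids].to_numpy(), g.loc[father_ids].to_numpy(), params.rho_am, mate_rng
    )
    couples = [(mother_ids[i], father_ids[pairing[i]]) for i in range(n_families)]

    fam_rng = substream(seed, "meiosis")
    pedigree, haps, truth = build_families(
        founders, couples, n_offspring_per_couple, pair_fraction,
        father_masked_share, fam_rng,
    )
    truth_haps = haps
    if switch_error_rate > 0:
        haps = add_switch_errors(haps, switch_error_rate, substream(seed, "switch"))
    pheno = simulate_phenotypes(
        pedigree, truth_haps, weights, params, substream(seed, "phenotypes")
    )
    return SyntheticDataset(
        gmap=gmap, haps=haps, truth_haps=truth_haps, pedigree=pedigree, truth=truth,
        phenotypes=pheno, weights=weights, freqs=freqs, params=params, seed=seed,
    )


def simulate_analysis_table(
    n_families: int,
    params: PhenoModelParams | None = None,
    seed: int = 0,
    n_offspring_per_couple=(1, 3),
    pair_fraction: float = 0.83,
    father_masked_share: float = 0.7,
) -> pd.DataFrame:
    """Score-level shortcut generator for calibration studies.

    Simulates the per-parent transmitted/non-transmitted score components
    directly (each haplotype-score half ~ N(0, 1/2), so parent and offspring
    total scores are standard normal) under the same causal structure as the
    genotype-level generator, skipping genotypes entirely.  Used for
    repeated-seed calibration (type-I error, coverage, recovery) where
    thousands of full genotype simulations would be wasteful.

    Columns mirror the pipeline's analysis frame: mt, pt, mnt, pnt (raw
    components; pnt/mnt NaN for the masked parent in pair families), pgs_t,
    pgs_nt (from truth, pre-imputation), outcomes, covariates and truth
    columns.
    """
    params = params or PhenoModelParams()
    params.validate()
    rng = substream(seed, "analysis_table")

    n_off = (
        np.full(n_families, n_offspring_per_couple, dtype=int)
        if isinstance(n_offspring_per_couple, int)
        else rng.integers(
            n_offspring_per_couple[0], n_offspring_per_couple[1] + 1, n_families
        )
    )
    n = int(n_off.sum())
    fam_of = np.repeat(np.arange(n_families), n_off)

    # parental total scores with assortative-mating correlation rho_am
    rho = params.rho_am
    gm = rng.standard_normal(n_families)
    gf = rho * gm + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_families)

    # split each parent score into transmitted/non-transmitted halves per child
    d_m = rng.normal(0.0, 0.5, n)
    d_f = rng.normal(0.0, 0.5, n)
    mt = gm[fam_of] / 2.0 + d_m
    mnt = gm[fam_of] / 2.0 - d_m
    pt = gf[fam_of] / 2.0 + d_f
    pnt = gf[fam_of] / 2.0 - d_f

    zg_off = _zscore(mt + pt)
    zg_m = _zscore(gm[fam_of])
    zg_f = _zscore(gf[fam_of])

    p_m = params.gamma * _zscore(gm) + rng.normal(0, params.parent_resid_sd, n_families)
    p_f = params.gamma * _zscore(gf) + rng.normal(0, params.parent_resid_sd, n_families)
    zp_m = _zscore(p_m[fam_of])
    zp_f = _zscore(p_f[fam_of])

    sex = (rng.random(n) < 0.5).astype(float)
    age = rng.uniform(*params.age_range, n)
    zage = _zscore(age)

    def latent():
        return (
            params.delta * zg_off
            + params.eta_m * zp_m
            + params.eta_f * zp_f
            + params.nurture_direct * (zg_m + zg_f)
            + params.beta_sex * sex
            + params.beta_age * zage
            + rng.normal(0.0, params.resid_sd, n)
        )

    smk_init = _liability_binary(latent(), params.prev_smoking_init)
    cig_day = 10.24 + 6.0 * latent()
    pack_years = 7.03 + 6.7 * latent()
    alc_gday = 6.74 + 8.5 * latent()
    cannabis = _liability_binary(latent(), params.prev_cannabis)
    init = smk_init > 0

    is_pair = rng.random(n_families) < pair_fraction
    father_masked = rng.random(n_families) < father_masked_share
    mask_m = (is_pair & father_masked)[fam_of]   # father masked -> mother observed
    mnt_obs = np.where((is_pair & ~father_masked)[fam_of], np.nan, mnt)
    pnt_obs = np.where(mask_m, np.nan, pnt)

    df = pd.DataFrame(
        {
            "individual_id": [f"fam{f:05d}_o{i}" for i, f in enumerate(fam_of)],
            "family_id": [f"fam{f:05d}" for f in fam_of],
            "mt": mt,
            "pt": pt,
            "mnt": mnt_obs,
            "pnt": pnt_obs,
            "pgs_t": mt + pt,
            "pgs_nt": mnt + pnt,
            "sex": sex,
            "age": age,
            "smk_init": smk_init,
            "cig_day": np.where(init, cig_day, np.nan),
            "pack_years": np.where(init, pack_years, np.nan),
            "alc_gday": alc_gday,
            "cannabis_ever": np.where(
                rng.random(n) < params.cannabis_measured_frac, cannabis, np.nan
            ),
            "mother_cig_day": 10.24 + 6.0 * zp_m,
            "father_cig_day": 10.24 + 6.0 * zp_f,
            "mother_pack_years": 7.03 + 6.7 * zp_m,
            "father_pack_years": 7.03 + 6.7 * zp_f,
            "true_g_z": zg_off,
            "true_g_mother_z": zg_m,
            "true_g_father_z": zg_f,
            "true_p_mother_z": zp_m,
            "true_p_father_z": zp_f,
        }
    )
    return df
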