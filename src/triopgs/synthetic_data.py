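"""Synthetic trio cohorts with liability-threshold ascertainment.

The generator produces the statistical structure the downstream analyses
assume: two parents per family drawn under random mating and linkage
equilibrium, children by Mendelian transmission, a polygenic liability
(true PGS plus Gaussian environment) that ascertains probands from the top
quantile of the population liability distribution, binary comorbid outcomes
with configurable per-SD log-odds effects of the true PGS, and discovery
summary statistics whose weights are the true effects plus sampling noise
scaled by a discovery-sample-size proxy.

Under ascertainment, children are selected partly on the within-family
Mendelian deviation of their polygenic score, so the proband PGS exceeds the
mid-parent expectation on average — exactly the over-transmission signal the
polygenic transmission disequilibrium test measures. With no ascertainment
(quantile 1) the cohort is a null for that test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .sumstats_io import (
    GenotypePanel,
    SummaryStats,
    write_pedigree,
    write_sumstats,
    write_traw,
    write_vcf,
)

log = logging.getLogger(__name__)

#: allele pairs used by default — strand-unambiguous only, so harmonization
#: retains every simulated variant unless ambiguity is injected explicitly
UNAMBIGUOUS_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
AMBIGUOUS_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class OutcomeModel:
    """Binary outcome: P(y=1) = logistic(intercept + effect * standardized true PGS)."""

    name: str
    intercept: float
    effect: float = 0.0


def _default_outcomes() -> list[OutcomeModel]:
    # prevalences mirror a clinic-ascertained ADHD cohort's sleep comorbidity
    # rates; effects default to zero (no PGS-outcome association)
    prev = {
        "insomnia": 0.256,
        "restless_sleep": 0.559,
        "sleep_quality": 0.197,
        "nightmares": 0.184,
        "hypersomnia": 0.041,
    }
    return [OutcomeModel(k, float(np.log(p / (1 - p)))) for k, p in prev.items()]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for a synthetic trio study.

    n_trios may be an int (same size for every cohort) or a tuple with one
    entry per cohort. h2_pgs is the fraction of liability variance carried by
    the scored variants; ascertainment_quantile q means probands are drawn
    from the top q of the population liability distribution (q=1: none).
    discovery_n scales the sampling noise of the emitted discovery weights
    (np.inf gives noise-free weights). sibling_rate is the fraction of
    families with one extra non-ascertained child (for family clustering).
    """

    n_trios: int | tuple[int, ...] = 328
    n_variants: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 2_000
    h2_pgs: float = 0.05
    ascertainment_quantile: float = 0.05
    outcome_models: tuple[OutcomeModel, ...] = field(
        default_factory=lambda: tuple(_default_outcomes())
    )
    n_cohorts: int = 1
    missing_rate: float = 0.0
    seed: int = 0
    discovery_n: float = 100_000.0
    sibling_rate: float = 0.05
    family_sd: float = 0.0
    female_fraction: float = 0.133
    n_batches: int = 3
    adhd_medication_rate: float = 0.303
    sleep_medication_rate: float = 0.148
    parent_report_agreement: float = 0.9
    ambiguous_fraction: float = 0.0
    swap_fraction: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not (0 <= self.h2_pgs < 1):
            raise ValueError("h2_pgs must be in [0, 1)")
        if not (0 < self.ascertainment_quantile <= 1):
            raise ValueError("ascertainment_quantile must be in (0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if self.h2_pgs > 0 and self.n_causal < 1:
            raise ValueError("n_causal must be >= 1 when h2_pgs > 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for m in self.outcome_models:
            if not np.isfinite(m.intercept):
                raise ValueError(f"outcome {m.name!r}: intercept must be finite "
                                 "(a zero/one prevalence is not simulable)")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")

    @property
    def cohort_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_trios, int):
            return (self.n_trios,) * self.n_cohorts
        if len(self.n_trios) != self.n_cohorts:
            raise ValueError("len(n_trios) must equal n_cohorts")
        return tuple(self.n_trios)


@dataclass
class GeneticArchitecture:
    """Shared truth across cohorts: allele frequencies, effects, alleles."""

    maf: np.ndarray            # alt-allele population frequency
    beta: np.ndarray           # true per-alt-allele liability effect (0 for non-causal)
    causal: np.ndarray         # bool mask
    ref: np.ndarray
    alt: np.ndarray
    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    pgs_mean: float            # population mean/SD of the raw true PGS
    pgs_sd: float

    def standardize(self, raw_pgs: np.ndarray) -> np.ndarray:
        if self.pgs_sd == 0:
            return np.zeros_like(raw_pgs)
        return (raw_pgs - self.pgs_mean) / self.pgs_sd


@dataclass
class TrioCohort:
    """One simulated cohort: genotype panel, phenotypes, and the truth table."""

    panel: GenotypePanel
    phenotypes: pd.DataFrame
    truth: pd.DataFrame        # sample_id, true_pgs_z, liability (children only for liability)
    label: str = "cohort1"


@dataclass
class SimulatedStudy:
    cohorts: list[TrioCohort]
    sumstats: SummaryStats
    architecture: GeneticArchitecture
    config: SimulationConfig


# ---------------------------------------------------------------------------
# primitives


def draw_architecture(cfg: SimulationConfig, rng: np.random.Generator) -> GeneticArchitecture:
    m = cfg.n_variants
    maf = rng.uniform(*cfg.maf_range, size=m)
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=cfg.n_causal, replace=False)] = True
    beta = np.zeros(m)
    beta[causal] = rng.normal(0.0, 1.0, size=cfg.n_causal)

    n_amb = int(round(cfg.ambiguous_fraction * m))
    pair_pool = np.array(UNAMBIGUOUS_PAIRS, dtype=object)
    pairs = pair_pool[rng.integers(0, len(pair_pool), size=m)]
    if n_amb:
        amb_idx = rng.choice(m, size=n_amb, replace=False)
        amb_pool = np.array(AMBIGUOUS_PAIRS, dtype=object)
        pairs[amb_idx] = amb_pool[rng.integers(0, len(amb_pool), size=n_amb)]
    ref = np.array([p[0] for p in pairs], dtype=object)
    alt = np.array([p[1] for p in pairs], dtype=object)

    chrom = ((np.arange(m) % 22) + 1).astype(str)
    pos = (np.arange(m) // 22 + 1) * 1000
    vid = np.array([f"rs{j + 1}" for j in range(m)], dtype=object)

    mean = float(np.sum(2 * maf * beta))
    var = float(np.sum(beta**2 * 2 * maf * (1 - maf)))
    return GeneticArchitecture(
        maf=maf, beta=beta, causal=causal, ref=ref, alt=alt,
        variant_id=vid, chrom=chrom, pos=pos,
        pgs_mean=mean, pgs_sd=float(np.sqrt(var)),
    )


def simulate_parents(
    cfg: SimulationConfig, rng: np.random.Generator, n_parents: int,
    maf: np.ndarray | None = None,
) -> np.ndarray:
    """Parental dosages ~ Binomial(2, maf_j), independent across variants (no LD)."""
    if maf is None:
        maf = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
    return rng.binomial(2, maf, size=(n_parents, len(maf))).astype(float)


def transmit(
    father: np.ndarray, mother: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian transmission: one uniformly chosen allele from each parent.

    A parent with dosage d transmits an alt allele with probability d/2.
    Missing parental dosage propagates to a missing child dosage.
    """
    father = np.asarray(father, dtype=float)
    mother = np.asarray(mother, dtype=float)
    from_f = (rng.random(father.shape) < father / 2.0).astype(float)
    from_m = (rng.random(mother.shape) < mother / 2.0).astype(float)
    child = from_f + from_m
    child[np.isnan(father) | np.isnan(mother)] = np.nan
    return child


def mendelian_consistency_rate(panel: GenotypePanel) -> float:
    """Fraction of non-missing trio genotypes compatible with transmission.

    A child dosage c is compatible with parental dosages (f, m) iff
    min(f) + min(m) <= c <= max(f) + max(m), where a parent with dosage 0/1/2
    can transmit 0/{0,1}/1 alt alleles.
    """
    s = panel.samples
    idx = {sid: i for i, sid in enumerate(s["sample_id"])}
    child_rows = s[s["role"].isin(["proband", "sibling"])]
    checked = matched = 0
    for r in child_rows.itertuples():
        fi, mi = idx.get(r.father_id), idx.get(r.mother_id)
        if fi is None or mi is None:
            continue
        c, f, m = panel.dosages[idx[r.sample_id]], panel.dosages[fi], panel.dosages[mi]
        ok = ~(np.isnan(c) | np.isnan(f) | np.isnan(m))
        lo = (f == 2).astype(float) + (m == 2).astype(float)
        hi = (f > 0).astype(float) + (m > 0).astype(float)
        good = (c >= lo) & (c <= hi)
        checked += int(ok.sum())
        matched += int((good & ok).sum())
    if checked == 0:
        raise ValueError("no complete trios to check")
    return matched / checked


# ---------------------------------------------------------------------------
# cohort assembly


def ascertain_probands(
    cfg: SimulationConfig,
    arch: GeneticArchitecture,
    rng: np.random.Generator,
    n_trios: int,
    max_batches: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate trios until n_trios children pass the liability threshold.

    Liability = sqrt(h2_pgs) * standardized true PGS + sqrt(1-h2_pgs) * e,
    e ~ N(0,1); a child is ascertained when liability exceeds the population
    (1 - q) quantile. Returns (fathers, mothers, children, child z-PGS,
    child liability).
    """
    q = cfg.ascertainment_quantile
    thresh = -np.inf if q >= 1 else norm.ppf(1 - q)
    batch = max(32, int(np.ceil(n_trios / q * 1.25)))
    kept_f, kept_m, kept_c, kept_z, kept_l = [], [], [], [], []
    n_kept = 0
    for _ in range(max_batches):
        fathers = simulate_parents(cfg, rng, batch, arch.maf)
        mothers = simulate_parents(cfg, rng, batch, arch.maf)
        children = transmit(fathers, mothers, rng)
        zpgs = arch.standardize(children @ arch.beta)
        liab = np.sqrt(cfg.h2_pgs) * zpgs + np.sqrt(1 - cfg.h2_pgs) * rng.normal(size=batch)
        keep = np.flatnonzero(liab > thresh)[: n_trios - n_kept]
        if keep.size:
            kept_f.append(fathers[keep])
            kept_m.append(mothers[keep])
            kept_c.append(children[keep])
            kept_z.append(zpgs[keep])
            kept_l.append(liab[keep])
            n_kept += keep.size
        if n_kept >= n_trios:
            return (
                np.vstack(kept_f), np.vstack(kept_m), np.vstack(kept_c),
                np.concatenate(kept_z), np.concatenate(kept_l),
            )
    raise RuntimeError(
        f"could not ascertain {n_trios} trios in {max_batches} batches "
        f"(quantile {q}); increase max_batches"
    )


def simulate_outcomes(
    cfg: SimulationConfig,
    child_ids: list[str],
    family_ids: list[str],
    child_zpgs: np.ndarray,
    child_sex: np.ndarray,
    batches: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binary outcomes and covariates for the children of a cohort.

    Each outcome is Bernoulli with logit = intercept + effect * z-PGS
    (+ a shared family intercept when family_sd > 0). Covariates (age,
    medication flags) are independent of genotype. A parent-report replica of
    each outcome keeps positives with probability parent_report_agreement.
    """
    n = len(child_ids)
    fam_index = pd.factorize(np.asarray(family_ids))[0]
    fam_effect = (
        rng.normal(0.0, cfg.family_sd, size=fam_index.max() + 1)[fam_index]
        if cfg.family_sd > 0 else np.zeros(n)
    )
    out = pd.DataFrame({
        "sample_id": child_ids,
        "family_id": family_ids,
        "age": np.round(rng.uniform(5, 18, size=n), 1),
        "sex": child_sex,
        "batch": batches,
        "adhd_medication": rng.binomial(1, cfg.adhd_medication_rate, size=n),
        "sleep_medication": rng.binomial(1, cfg.sleep_medication_rate, size=n),
    })
    for m in cfg.outcome_models:
        p = expit(m.intercept + m.effect * child_zpgs + fam_effect)
        y = rng.binomial(1, p)
        out[m.name] = y
        out[f"{m.name}_parent"] = y * rng.binomial(1, cfg.parent_report_agreement, size=n)
    return out


def simulate_cohort(
    cfg: SimulationConfig,
    arch: GeneticArchitecture,
    rng: np.random.Generator,
    n_trios: int,
    label: str = "cohort1",
) -> TrioCohort:
    """One complete trio cohort: ascertained probands, optional siblings,
    MCAR missingness, phenotypes, pedigree and truth tables."""
    fathers, mothers, probands, zpgs, liab = ascertain_probands(cfg, arch, rng, n_trios)

    n_sib = rng.binomial(1, cfg.sibling_rate, size=n_trios)
    sib_fam = np.flatnonzero(n_sib)
    siblings = transmit(fathers[sib_fam], mothers[sib_fam], rng) if sib_fam.size else np.empty((0, cfg.n_variants))
    sib_z = arch.standardize(siblings @ arch.beta) if sib_fam.size else np.empty(0)

    fam = [f"{label.upper()}F{i + 1:04d}" for i in range(n_trios)]
    rows, dos, zs, liabs = [], [], [], []
    batches = np.array([f"batch{b + 1}" for b in rng.integers(0, cfg.n_batches, size=n_trios)])
    child_sex = np.where(rng.random(n_trios) < cfg.female_fraction, 2, 1)
    sib_sex = np.where(rng.random(sib_fam.size) < cfg.female_fraction, 2, 1)

    for i in range(n_trios):
        fid = fam[i]
        pid, faid, moid = f"{fid}-PR", f"{fid}-FA", f"{fid}-MO"
        rows.append((fid, faid, "", "", "1", "father", batches[i]))
        rows.append((fid, moid, "", "", "2", "mother", batches[i]))
        rows.append((fid, pid, faid, moid, str(child_sex[i]), "proband", batches[i]))
        dos.extend([fathers[i], mothers[i], probands[i]])
        zs.extend([np.nan, np.nan, zpgs[i]])
        liabs.extend([np.nan, np.nan, liab[i]])
    for k, i in enumerate(sib_fam):
        fid = fam[i]
        rows.append((fid, f"{fid}-S1", f"{fid}-FA", f"{fid}-MO", str(sib_sex[k]), "sibling", batches[i]))
        dos.append(siblings[k])
        zs.append(sib_z[k])
        liabs.append(np.nan)

    samples = pd.DataFrame(
        rows, columns=["family_id", "sample_id", "father_id", "mother_id", "sex", "role", "batch"]
    )
    dosages = np.vstack(dos)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(mask, np.nan, dosages)

    # parental z-PGS for the truth table (useful for validation)
    parent_rows = samples["role"].isin(["father", "mother"]).to_numpy()
    all_z = np.asarray(zs, dtype=float)
    raw = np.vstack(dos) @ arch.beta  # pre-missingness dosages define the truth
    all_z[parent_rows] = arch.standardize(raw[parent_rows])

    variants = pd.DataFrame({
        "variant_id": arch.variant_id, "chrom": arch.chrom, "pos": arch.pos,
        "ref": arch.ref, "alt": arch.alt,
    })
    panel = GenotypePanel.from_parts(samples, variants, dosages)

    child_mask = samples["role"].isin(["proband", "sibling"]).to_numpy()
    phen = simulate_outcomes(
        cfg,
        list(samples.loc[child_mask, "sample_id"]),
        list(samples.loc[child_mask, "family_id"]),
        all_z[child_mask],
        samples.loc[child_mask, "sex"].astype(int).to_numpy(),
        samples.loc[child_mask, "batch"].to_numpy(),
        rng,
    )
    truth = pd.DataFrame({
        "sample_id": samples["sample_id"],
        "true_pgs_z": all_z,
        "liability": liabs,
    })
    return TrioCohort(panel=panel, phenotypes=phen, truth=truth, label=label)


def emit_discovery_sumstats(
    cfg: SimulationConfig, arch: GeneticArchitecture, rng: np.random.Generator
) -> SummaryStats:
    """Discovery GWAS stand-in: estimated weight = true effect + noise.

    The per-variant standard error follows the usual GWAS scaling
    1/sqrt(2 p (1-p) N); p-values are two-sided normal on the resulting
    z-score, so null variants have uniform p-values at any noise level.
    A swap_fraction of rows is emitted with effect/other alleles exchanged
    (weight negated) to exercise harmonization.
    """
    m = cfg.n_variants
    se = (
        np.zeros(m) if np.isinf(cfg.discovery_n)
        else 1.0 / np.sqrt(2 * arch.maf * (1 - arch.maf) * cfg.discovery_n)
    )
    eps = rng.normal(size=m)
    weight = arch.beta + se * eps
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, weight / np.where(se > 0, se, 1.0),
                     np.where(arch.beta != 0, np.inf, eps))
    pvalue = np.clip(2 * norm.sf(np.abs(z)), 1e-300, 1.0)

    eff, oth, w, eaf = arch.alt.copy(), arch.ref.copy(), weight.copy(), arch.maf.copy()
    swap = rng.random(m) < cfg.swap_fraction
    eff[swap], oth[swap] = arch.ref[swap], arch.alt[swap]
    w[swap] = -w[swap]
    eaf[swap] = 1 - eaf[swap]
    df = pd.DataFrame({
        "variant_id": arch.variant_id, "chrom": arch.chrom, "pos": arch.pos,
        "effect_allele": eff, "other_allele": oth,
        "weight": w, "pvalue": pvalue, "eaf": eaf,
    })
    return SummaryStats.from_frame(df)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Full study: shared architecture, n_cohorts trio cohorts, discovery sumstats.

    All randomness flows from cfg.seed through per-stage spawned streams, so
    identical configs give byte-identical outputs.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(2 + cfg.n_cohorts)
    arch = draw_architecture(cfg, np.random.default_rng(streams[0]))
    sumstats = emit_discovery_sumstats(cfg, arch, np.random.default_rng(streams[1]))
    cohorts = [
        simulate_cohort(
            cfg, arch, np.random.default_rng(streams[2 + i]), n, label=f"cohort{i + 1}"
        )
        for i, n in enumerate(cfg.cohort_sizes)
    ]
    return SimulatedStudy(cohorts=cohorts, sumstats=sumstats, architecture=arch, config=cfg)


def write_cohort(cohort: TrioCohort, outdir: str | Path, fmt: str = "traw") -> dict[str, Path]:
    """Write a cohort's genotypes (+pedigree, phenotypes, truth) as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.fam",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
    }
    if fmt == "traw":
        paths["genotypes"] = outdir / "genotypes.traw"
        write_traw(cohort.panel, paths["genotypes"])
    elif fmt == "vcf":
        paths["genotypes"] = outdir / "genotypes.vcf"
        write_vcf(cohort.panel, paths["genotypes"])
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    write_pedigree(cohort.panel, paths["pedigree"])
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
    log.info("wrote cohort %s to %s", cohort.label, outdir)
    return paths


def write_study(study: SimulatedStudy, outdir: str | Path, fmt: str = "traw") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"sumstats": outdir / "sumstats.tsv", "cohorts": {}}
    write_sumstats(study.sumstats, paths["sumstats"])
    for cohort in study.cohorts:
        paths["cohorts"][cohort.label] = write_cohort(cohort, outdir / cohort.label, fmt=fmt)
    return paths
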