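"""Readers, writers and harmonization for GWAS summary statistics and trio genotype panels.

Summary statistics are per-variant effect-allele weights (log odds ratios or
betas) with discovery p-values. Before scoring, each weight must be expressed
per copy of the target panel's *alt* allele: alleles are matched by identity,
by swapping effect/other (negating the weight), or by strand complementation,
and strand-ambiguous A/T and C/G variants are discarded because their
orientation cannot be resolved without strand information.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
BASES = frozenset("ACGT")

#: canonical summary-statistic columns, in file order
SUMSTATS_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "weight",
    "pvalue",
    "eaf",
)

PEDIGREE_COLUMNS = (
    "family_id",
    "sample_id",
    "father_id",
    "mother_id",
    "sex",
    "role",
    "batch",
)

ROLES = frozenset({"father", "mother", "proband", "sibling"})

#: default phenotype-table columns treated as covariates (everything else must
#: be a binary 0/1 outcome)
DEFAULT_COVARIATE_COLUMNS = frozenset(
    {"age", "sex", "batch", "adhd_medication", "sleep_medication", "family_id"}
)


class SumstatsError(ValueError):
    """Raised for unrecoverable summary-statistic or harmonization problems."""


@dataclass
class SummaryStats:
    """Validated per-variant discovery weights.

    ``table`` holds the canonical columns: variant_id, chrom, pos,
    effect_allele, other_allele, weight (log OR / beta), pvalue, eaf
    (effect-allele frequency; NaN when unavailable).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryStats":
        """Validate a raw frame, dropping rows that violate the invariants.

        Drops (with counts logged): non-ACGT or identical alleles, non-finite
        weights, p-values outside (0, 1], duplicate variant ids (first kept).
        Raises :class:`SumstatsError` if no valid rows remain.
        """
        df = df.copy()
        n_in = len(df)
        for col in ("effect_allele", "other_allele"):
            df[col] = df[col].astype(str).str.upper()
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
        df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
        df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
        if "eaf" not in df.columns:
            df["eaf"] = np.nan

        ok = (
            df["effect_allele"].isin(BASES)
            & df["other_allele"].isin(BASES)
            & (df["effect_allele"] != df["other_allele"])
            & np.isfinite(df["weight"])
            & (df["pvalue"] > 0)
            & (df["pvalue"] <= 1)
            & df["pos"].notna()
        )
        n_invalid = int((~ok).sum())
        df = df[ok]
        n_dup = int(df["variant_id"].duplicated().sum())
        df = df[~df["variant_id"].duplicated()]
        if n_invalid or n_dup:
            log.warning(
                "sumstats: dropped %d invalid rows and %d duplicate ids (of %d)",
                n_invalid, n_dup, n_in,
            )
        if df.empty:
            raise SumstatsError("no valid summary-statistic rows after validation")
        df = df[list(SUMSTATS_COLUMNS)].reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        return cls(df)


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    scale: str = "logOR",
) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    path
        TSV with a header row.
    column_map
        Mapping from canonical names (``variant_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``weight``, ``pvalue``, ``eaf``)
        to the file's column names. Unmapped names default to the canonical
        spelling. ``eaf`` is optional.
    scale
        Scale of the ``weight`` column: ``"logOR"`` or ``"beta"`` (stored
        as-is) or ``"OR"`` (log-transformed; OR=1 maps to weight 0).
    """
    if scale not in {"logOR", "beta", "OR"}:
        raise SumstatsError(f"unknown weight scale {scale!r}")
    cmap = {c: c for c in SUMSTATS_COLUMNS}
    cmap.update(column_map or {})
    raw = pd.read_csv(path, sep="\t", dtype={cmap["variant_id"]: str, cmap["chrom"]: str})
    required = [c for c in SUMSTATS_COLUMNS if c != "eaf"]
    for canon in required:
        if cmap[canon] not in raw.columns:
            raise SumstatsError(
                f"required column {cmap[canon]!r} (for {canon!r}) missing from {path}"
            )
    df = pd.DataFrame({canon: raw[cmap[canon]] for canon in required})
    df["eaf"] = raw[cmap["eaf"]] if cmap["eaf"] in raw.columns else np.nan
    if scale == "OR":
        w = pd.to_numeric(df["weight"], errors="coerce")
        bad = ~(w > 0)
        if bad.any():
            log.warning("sumstats: %d rows with non-positive OR dropped", int(bad.sum()))
        df.loc[bad, "weight"] = np.nan
        df["weight"] = np.log(w.where(~bad))
    return SummaryStats.from_frame(df)


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    ss.table.to_csv(path, sep="\t", index=False, na_rep="NA")
    log.info("wrote %d sumstats rows to %s", len(ss), path)


# ---------------------------------------------------------------------------
# genotype panel


@dataclass
class GenotypePanel:
    """Samples × variants dosage matrix with pedigree and variant metadata.

    ``samples``: sample_id, family_id, father_id, mother_id, sex, role, batch,
    complete_trio. ``variants``: variant_id, chrom, pos, ref, alt, af_alt, maf.
    ``dosages``: float array counting alt-allele copies, NaN = missing.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    @staticmethod
    def allele_frequencies(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(alt-allele frequency, folded minor-allele frequency) per variant."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(dosages, axis=0) / 2.0
        af = np.where(np.isnan(af), 0.0, af)
        return af, np.minimum(af, 1.0 - af)

    @classmethod
    def from_parts(
        cls,
        samples: pd.DataFrame,
        variants: pd.DataFrame,
        dosages: np.ndarray,
    ) -> "GenotypePanel":
        """Assemble a panel, computing allele frequencies and trio flags."""
        samples = samples.reset_index(drop=True).copy()
        variants = variants.reset_index(drop=True).copy()
        dosages = np.asarray(dosages, dtype=float)
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        af, maf = cls.allele_frequencies(dosages)
        variants["af_alt"] = af
        variants["maf"] = maf
        present = set(samples["sample_id"])
        samples["complete_trio"] = [
            (r.role == "proband")
            and (r.father_id in present)
            and (r.mother_id in present)
            for r in samples.itertuples()
        ]
        return cls(samples, variants, dosages)


# ---------------------------------------------------------------------------
# harmonization


@dataclass
class HarmonizedWeights:
    """Discovery weights aligned to a panel's alt alleles.

    ``variant_index`` are integer positions into the panel's variant table;
    ``weight`` is the sign-corrected log OR per alt-allele copy. ``report`` is
    the per-variant flag table and ``counts`` the drop accounting, with
    n_input = n_retained + n_dropped_no_overlap + n_dropped_ambiguous
    + n_dropped_unmatched + n_dropped_maf.
    """

    variant_index: np.ndarray
    weight: np.ndarray
    pvalue: np.ndarray
    flag: np.ndarray
    report: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variant_index)


def _align_alleles(eff: str, oth: str, ref: str, alt: str) -> tuple[int, str] | None:
    """Return (sign, provenance flag) aligning an (effect, other) pair to (ref, alt).

    sign +1 keeps the weight (effect allele is alt), −1 negates it. None when
    the pairs cannot be reconciled even after strand complementation.
    """
    if (eff, oth) == (alt, ref):
        return 1, "direct"
    if (eff, oth) == (ref, alt):
        return -1, "allele_swapped"
    ceff, coth = COMPLEMENT[eff], COMPLEMENT[oth]
    if (ceff, coth) == (alt, ref):
        return 1, "strand_flipped"
    if (ceff, coth) == (ref, alt):
        return -1, "strand_flipped_and_swapped"
    return None


def harmonize(
    ss: SummaryStats,
    panel: GenotypePanel,
    maf_threshold: float = 0.05,
    drop_ambiguous: bool = True,
) -> HarmonizedWeights:
    """Align summary-statistic weights to a genotype panel.

    Matching is by ``variant_id``, falling back to chrom:pos for rows whose id
    is missing. A/T and C/G pairs are dropped when ``drop_ambiguous`` (their
    strand cannot be resolved); retained variants must have panel MAF strictly
    above ``maf_threshold``. Weights keep their magnitude: only the sign is
    corrected so every weight counts alt-allele copies.
    """
    if panel.n_variants == 0:
        raise SumstatsError("empty genotype panel")
    st = ss.table
    pv = panel.variants
    id_to_idx = {v: i for i, v in enumerate(pv["variant_id"])}
    pos_to_idx = {(c, p): i for i, (c, p) in enumerate(zip(pv["chrom"].astype(str), pv["pos"]))}

    n_input = len(st)
    rows: list[tuple[int, float, float, str]] = []
    flags: list[str] = []
    counts = dict.fromkeys(
        ("n_input", "n_retained", "n_dropped_no_overlap", "n_dropped_ambiguous",
         "n_dropped_unmatched", "n_dropped_maf"), 0)
    counts["n_input"] = n_input

    eff_a = st["effect_allele"].to_numpy()
    oth_a = st["other_allele"].to_numpy()
    weights = st["weight"].to_numpy()
    pvals = st["pvalue"].to_numpy()
    vids = st["variant_id"].to_numpy()
    chroms = st["chrom"].astype(str).to_numpy()
    poss = st["pos"].to_numpy()

    for k in range(n_input):
        vid = vids[k]
        idx = id_to_idx.get(vid)
        if idx is None:
            idx = pos_to_idx.get((chroms[k], poss[k])) if (vid is None or vid == "" or pd.isna(vid)) else None
        if idx is None:
            counts["n_dropped_no_overlap"] += 1
            flags.append("no_overlap")
            continue
        eff, oth = eff_a[k], oth_a[k]
        if drop_ambiguous and COMPLEMENT[eff] == oth:
            counts["n_dropped_ambiguous"] += 1
            flags.append("ambiguous")
            continue
        res = _align_alleles(eff, oth, pv["ref"].iat[idx], pv["alt"].iat[idx])
        if res is None:
            counts["n_dropped_unmatched"] += 1
            flags.append("unmatched_alleles")
            continue
        sign, flag = res
        if pv["maf"].iat[idx] <= maf_threshold:
            counts["n_dropped_maf"] += 1
            flags.append("low_maf")
            continue
        rows.append((idx, sign * weights[k], pvals[k], flag))
        flags.append(flag)

    counts["n_retained"] = len(rows)
    if not rows:
        raise SumstatsError("no summary-statistic variants overlap the panel after filtering")

    report = pd.DataFrame({"variant_id": vids, "flag": flags})
    vi = np.array([r[0] for r in rows], dtype=np.intp)
    hw = HarmonizedWeights(
        variant_index=vi,
        weight=np.array([r[1] for r in rows]),
        pvalue=np.array([r[2] for r in rows]),
        flag=np.array([r[3] for r in rows], dtype=object),
        report=report,
        counts=counts,
    )
    log.info("harmonized %d/%d variants (%s)", len(hw), n_input,
             ", ".join(f"{k}={v}" for k, v in counts.items() if k.startswith("n_dropped")))
    return hw


def write_harmonization_report(hw: HarmonizedWeights, path: str | Path) -> None:
    """Per-variant flag TSV with a trailing summary-count block (commented)."""
    path = Path(path)
    hw.report.to_csv(path, sep="\t", index=False)
    with open(path, "a") as fh:
        for k, v in hw.counts.items():
            fh.write(f"# {k}\t{v}\n")
    log.info("wrote harmonization report to %s", path)


# ---------------------------------------------------------------------------
# genotype / pedigree / phenotype readers


def _read_pedigree(path: str | Path) -> pd.DataFrame:
    """FAM-like whitespace table: family, individual, father, mother, sex, role[, batch]."""
    ped = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if ped.shape[1] < 6:
        raise ValueError(f"pedigree file {path} needs >= 6 columns, found {ped.shape[1]}")
    ped = ped.iloc[:, :7]
    ped.columns = list(PEDIGREE_COLUMNS[: ped.shape[1]])
    if "batch" not in ped.columns:
        ped["batch"] = "batch1"
    bad = ~ped["role"].isin(ROLES)
    if bad.any():
        raise ValueError(
            f"pedigree roles must be one of {sorted(ROLES)}; got {sorted(ped.loc[bad, 'role'].unique())}"
        )
    for col in ("father_id", "mother_id"):
        ped[col] = ped[col].replace({"0": "", "NA": ""})
    return ped


def _read_traw(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """PLINK .traw: CHR SNP (C)M POS COUNTED ALT then FID_IID sample columns.

    The COUNTED allele is the one the dosages count; we store it as the
    panel's alt allele and the ALT column as ref.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    meta_cols = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    variants = pd.DataFrame(
        {
            "variant_id": df["SNP"].astype(str),
            "chrom": df["CHR"].astype(str),
            "pos": df["POS"].astype(np.int64),
            "ref": df["ALT"].astype(str),
            "alt": df["COUNTED"].astype(str),
        }
    )
    dosages = df[sample_cols].to_numpy(dtype=float).T  # samples x variants
    sample_ids = [c.split("_", 1)[1] if "_" in c else c for c in sample_cols]
    return variants, dosages, sample_ids


def _read_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Biallelic-SNP VCF; GT field converted to alt-allele dosage."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    recs, rows = [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        recs.append((v.ID or "", v.CHROM, v.POS, v.REF, v.ALT[0]))
        rows.append(remap[np.asarray(v.gt_types)])
    vcf.close()
    variants = pd.DataFrame(recs, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return variants, dosages, sample_ids


def read_genotypes(
    genotype_path: str | Path,
    pedigree_path: str | Path,
    phenotype_path: str | Path | None = None,
    covariate_columns: frozenset[str] | set[str] = DEFAULT_COVARIATE_COLUMNS,
) -> tuple[GenotypePanel, pd.DataFrame | None]:
    """Load genotypes (VCF or PLINK .traw), attach pedigree roles, read phenotypes.

    Samples present in the pedigree but not genotyped are excluded with a
    warning (and vice versa). Phenotype columns not listed as covariates are
    treated as binary outcomes and must be 0, 1 or missing.
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix == ".vcf" or genotype_path.name.endswith(".vcf.gz"):
        variants, dosages, sample_ids = _read_vcf(genotype_path)
    elif genotype_path.suffix == ".traw":
        variants, dosages, sample_ids = _read_traw(genotype_path)
    else:
        raise ValueError(f"unrecognized genotype format: {genotype_path}")

    ped = _read_pedigree(pedigree_path)
    geno_ids = pd.Index(sample_ids)
    missing_geno = ped[~ped["sample_id"].isin(geno_ids)]
    if len(missing_geno):
        log.warning(
            "%d pedigree samples have no genotypes and are excluded: %s",
            len(missing_geno), ", ".join(missing_geno["sample_id"].head(5)),
        )
    ped = ped[ped["sample_id"].isin(geno_ids)].reset_index(drop=True)
    extra = geno_ids.difference(ped["sample_id"])
    if len(extra):
        log.warning("%d genotyped samples absent from pedigree are excluded", len(extra))
    pos = {s: i for i, s in enumerate(sample_ids)}
    order = [pos[s] for s in ped["sample_id"]]
    panel = GenotypePanel.from_parts(ped, variants, dosages[order])

    phenos = None
    if phenotype_path is not None:
        phenos = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in phenos.columns:
            raise ValueError("phenotype table must have a sample_id column")
        outcome_cols = [
            c for c in phenos.columns
            if c != "sample_id" and c not in covariate_columns and not c.endswith("_parent")
        ]
        for col in outcome_cols + [c for c in phenos.columns if c.endswith("_parent")]:
            vals = phenos[col].dropna().unique()
            bad = set(vals) - {0, 1, 0.0, 1.0}
            if bad:
                raise ValueError(
                    f"phenotype column {col!r} must be binary 0/1; found values {sorted(bad)}"
                )
    return panel, phenos


# ---------------------------------------------------------------------------
# writers (plain-text formats)


def write_pedigree(panel: GenotypePanel, path: str | Path) -> None:
    out = panel.samples[list(PEDIGREE_COLUMNS)].copy()
    for col in ("father_id", "mother_id"):
        out[col] = out[col].replace({"": "0"}).fillna("0")
    out.to_csv(path, sep="\t", index=False, header=False)


def write_traw(panel: GenotypePanel, path: str | Path) -> None:
    v = panel.variants
    body = pd.DataFrame(
        {
            "CHR": v["chrom"],
            "SNP": v["variant_id"],
            "(C)M": 0,
            "POS": v["pos"],
            "COUNTED": v["alt"],
            "ALT": v["ref"],
        }
    )
    cols = {
        f"{row.family_id}_{row.sample_id}": panel.dosages[j]
        for j, row in enumerate(panel.samples.itertuples())
    }
    body = pd.concat([body, pd.DataFrame(cols)], axis=1)
    body.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal uncompressed VCFv4.2 with GT genotypes."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples["sample_id"]) + "\n")
        for j, v in enumerate(panel.variants.itertuples()):
            gts = "\t".join(gt_map.get(d, "./.") for d in panel.dosages[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")
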