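"""Genotype panel I/O, quality control, imputation and additive coding.

Supported input formats: VCF 4.x (GT field, biallelic sites), PLINK
``--recode A`` additive export (.raw), and plain TSV dosage (first column
subject id, remaining columns 0/1/2 codes with NA for missing).  After
reading, every column is oriented to count the minor allele defined on
the full panel, so MAF <= 0.5 throughout.

QC filters run in a fixed, logged order: subject call rate -> SNP call
rate -> MAF -> Hardy-Weinberg exact test.  Defaults: 0.95 call rate on
both margins, MAF >= 0.01, HWE alpha 1e-6.  Missing codes are imputed by
the SNP's observed mean dosage (2*MAF) before standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "read_genotypes",
    "write_tsv_dosage",
    "write_vcf",
    "hwe_exact_test",
    "apply_qc",
    "impute_and_standardize",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive codes (float; NaN = missing) plus annotation."""

    values: np.ndarray
    subject_ids: list[str]
    annotation: pd.DataFrame  # columns: snp_id, chrom, pos, gene, ref, alt

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (subjects x SNPs)")
        n, j = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match row count")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if len(self.annotation) != j:
            raise ValueError("annotation length does not match SNP count")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.annotation["snp_id"].tolist()

    def maf(self) -> np.ndarray:
        """Per-SNP allele frequency of the counted allele (post-orientation: minor)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.values, axis=0) / 2.0
        return freq

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=0)

    def call_rate_subjects(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=1)

    def orient_to_minor(self) -> "GenotypeMatrix":
        """Flip columns whose counted-allele frequency exceeds 0.5 (2 - g),
        swapping ref/alt in the annotation for flipped SNPs."""
        freq = self.maf()
        flip = freq > 0.5
        values = self.values.copy()
        values[:, flip] = 2.0 - values[:, flip]
        annot = self.annotation.copy()
        if flip.any():
            ref = annot["ref"].to_numpy().copy()
            alt = annot["alt"].to_numpy().copy()
            ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
            annot["ref"], annot["alt"] = ref, alt
        return GenotypeMatrix(values=values, subject_ids=list(self.subject_ids), annotation=annot)

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        values = self.values
        ids = list(self.subject_ids)
        annot = self.annotation
        if rows is not None:
            values = values[rows]
            ids = [s for s, keep in zip(self.subject_ids, rows) if keep]
        if cols is not None:
            values = values[:, cols]
            annot = annot.loc[cols].reset_index(drop=True)
        return GenotypeMatrix(values=values, subject_ids=ids, annotation=annot.reset_index(drop=True))


# ---------------------------------------------------------------------------
# reading / writing


def read_genotypes(path, fmt: str, annotation: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a genotype panel and orient to the panel-wide minor allele.

    fmt: "vcf" | "plink_raw" | "tsv_dosage".  For plink_raw / tsv_dosage an
    annotation table (snp_id, chrom, pos, gene, ref, alt) may be supplied;
    otherwise a minimal one is synthesised from the header.
    """
    if fmt == "vcf":
        gm = _read_vcf(path)
    elif fmt == "plink_raw":
        gm = _read_plink_raw(path, annotation)
    elif fmt == "tsv_dosage":
        gm = _read_tsv_dosage(path, annotation)
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")
    ids = gm.annotation["snp_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicated SNP id: {dup}")
    return gm.orient_to_minor()


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    rows, records = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"non-biallelic site {variant.ID or variant.POS}: ALT={variant.ALT}"
            )
        col = np.empty(len(subject_ids), dtype=float)
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col[i] = np.nan
            else:
                col[i] = float(a + b)
        rows.append(col)
        records.append(
            {
                "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "gene": variant.INFO.get("GENE", "unannotated"),
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
    if not rows:
        raise ValueError("VCF contains no variants")
    values = np.column_stack(rows)
    annotation = pd.DataFrame.from_records(records)
    return GenotypeMatrix(values=values, subject_ids=subject_ids, annotation=annotation)


def _read_plink_raw(path, annotation: pd.DataFrame | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in df.columns:
        raise ValueError("PLINK .raw file lacks an IID column")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    values = df[snp_cols].to_numpy(dtype=float)
    # header names are SNP_countedallele, e.g. rs123_G
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    _check_unique(snp_ids)
    annot = _resolve_annotation(snp_ids, annotation)
    return GenotypeMatrix(values=values, subject_ids=df["IID"].astype(str).tolist(), annotation=annot)


def _read_tsv_dosage(path, annotation: pd.DataFrame | None) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:])
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    subject_col = df.columns[0]
    snp_ids = header[1:]
    df.columns = [subject_col] + snp_ids
    values = df[snp_ids].to_numpy(dtype=float)
    annot = _resolve_annotation(snp_ids, annotation)
    return GenotypeMatrix(
        values=values, subject_ids=df[subject_col].astype(str).tolist(), annotation=annot
    )


def _check_unique(snp_ids: list[str]) -> None:
    seen = set()
    for sid in snp_ids:
        if sid in seen:
            raise ValueError(f"duplicated SNP id: {sid}")
        seen.add(sid)


def _resolve_annotation(snp_ids: list[str], annotation: pd.DataFrame | None) -> pd.DataFrame:
    if annotation is None:
        return pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": "0",
                "pos": np.arange(len(snp_ids)),
                "gene": "unannotated",
                "ref": "A",
                "alt": "G",
            }
        )
    annot = annotation.set_index("snp_id").reindex(snp_ids)
    if annot["chrom"].isna().any():
        missing = annot.index[annot["chrom"].isna()][0]
        raise ValueError(f"annotation missing SNP {missing}")
    return annot.reset_index()


def write_tsv_dosage(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.values, columns=gm.snp_ids)
    df.insert(0, "subject_id", gm.subject_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write hard genotype calls as a minimal VCF 4.2 with a GENE INFO tag."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.annotation["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.subject_ids) + "\n")
        annot = gm.annotation
        for k in range(gm.n_snps):
            row = annot.iloc[k]
            gts = [
                "./." if np.isnan(v) else gt_map[v] for v in gm.values[:, k]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\tGENE={row['gene']}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact conditional Hardy-Weinberg test (plain, not mid-p).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration.  Returns p in (0, 1].
    """
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0  # monomorphic: single attainable configuration

    # log P(het = h | allele counts) up to a common constant:
    #   log C(n, (n_minor-h)/2, h, ...) + h log 2
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = (n_major - hets) // 2
    lg = math.lgamma
    logp = np.array(
        [
            h * math.log(2) - lg(a + 1) - lg(h + 1) - lg(b + 1)
            for h, a, b in zip(hets, hom_min, hom_maj)
        ]
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    pv = p[p <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(pv, 1.0))


# ---------------------------------------------------------------------------
# QC filtering


@dataclass
class QcThresholds:
    snp_call_rate: float = 0.95
    subject_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_alpha: float = 1e-6

    def validate(self) -> None:
        for name in ("snp_call_rate", "subject_call_rate", "maf_min", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    thresholds: QcThresholds
    n_subjects_in: int = 0
    n_snps_in: int = 0
    n_subjects_out: int = 0
    n_snps_out: int = 0
    removed_subjects: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    snp_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    subject_call_rates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json_dict(self) -> dict:
        return {
            "thresholds": vars(self.thresholds),
            "n_subjects_in": self.n_subjects_in,
            "n_snps_in": self.n_snps_in,
            "n_subjects_out": self.n_subjects_out,
            "n_snps_out": self.n_snps_out,
            "removed_subjects": self.removed_subjects.to_dict(orient="records"),
            "removed_snps": self.removed_snps.to_dict(orient="records"),
        }


def apply_qc(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter subjects then SNPs; order: subject call rate -> SNP call rate
    -> MAF -> HWE.  Raises if nothing survives."""
    thresholds = thresholds or QcThresholds()
    thresholds.validate()
    report = QcReport(
        thresholds=thresholds, n_subjects_in=gm.n_subjects, n_snps_in=gm.n_snps
    )
    removed_subjects: list[dict] = []
    removed_snps: list[dict] = []

    # 1. subject call rate
    cr_subj = gm.call_rate_subjects()
    keep_rows = cr_subj >= thresholds.subject_call_rate
    for sid, cr in zip(np.asarray(gm.subject_ids)[~keep_rows], cr_subj[~keep_rows]):
        removed_subjects.append({"subject_id": sid, "reason": "call_rate", "value": float(cr)})
    gm = gm.subset(rows=keep_rows)
    if gm.n_subjects == 0:
        report.removed_subjects = pd.DataFrame(removed_subjects)
        raise ValueError("no subjects survive QC (subject call-rate filter)")

    # 2. SNP call rate
    cr_snp = gm.call_rate_snps()
    keep = cr_snp >= thresholds.snp_call_rate
    _log_removed(removed_snps, gm, ~keep, "call_rate", cr_snp)
    gm = gm.subset(cols=keep)

    # 3. MAF (recomputed on retained subjects; orientation already minor)
    if gm.n_snps:
        maf = np.minimum(gm.maf(), 1 - gm.maf())
        keep = maf >= thresholds.maf_min
        _log_removed(removed_snps, gm, ~keep, "maf", maf)
        gm = gm.subset(cols=keep)

    # 4. HWE exact test
    hwe_p = np.ones(gm.n_snps)
    if gm.n_snps:
        for k in range(gm.n_snps):
            col = gm.values[:, k]
            col = col[~np.isnan(col)]
            n2 = int((col == 2).sum())
            n1 = int((col == 1).sum())
            n0 = int((col == 0).sum())
            hwe_p[k] = hwe_exact_test(n2, n1, n0)
        keep = hwe_p >= thresholds.hwe_alpha
        _log_removed(removed_snps, gm, ~keep, "hwe", hwe_p)
        hwe_p = hwe_p[keep]
        gm = gm.subset(cols=keep)

    if gm.n_snps == 0:
        report.removed_snps = pd.DataFrame(removed_snps)
        raise ValueError("no SNPs survive QC")

    report.removed_subjects = pd.DataFrame(
        removed_subjects, columns=["subject_id", "reason", "value"]
    )
    report.removed_snps = pd.DataFrame(removed_snps, columns=["snp_id", "reason", "value"])
    report.n_subjects_out = gm.n_subjects
    report.n_snps_out = gm.n_snps
    report.snp_metrics = pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "call_rate": gm.call_rate_snps(),
            "maf": np.minimum(gm.maf(), 1 - gm.maf()),
            "hwe_p": hwe_p,
        }
    )
    report.subject_call_rates = pd.DataFrame(
        {"subject_id": gm.subject_ids, "call_rate": gm.call_rate_subjects()}
    )
    return gm, report


def _log_removed(log: list, gm: GenotypeMatrix, dropped: np.ndarray, reason: str, values: np.ndarray) -> None:
    for sid, v in zip(np.asarray(gm.snp_ids)[dropped], values[dropped]):
        log.append({"snp_id": sid, "reason": reason, "value": float(v)})


# ---------------------------------------------------------------------------
# imputation + standardization


def impute_and_standardize(gm: GenotypeMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean-impute missing dosages (per-SNP observed mean, i.e. 2*MAF on the
    counted allele) and scale each column to mean 0, SD 1.

    Returns the standardized matrix and a per-SNP (mean, sd) table needed to
    project new samples onto the same scale.
    """
    x = gm.values.astype(float).copy()
    means = np.nanmean(x, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(x))
    x[nan_rows, nan_cols] = means[nan_cols]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = gm.snp_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance SNP after imputation: {bad}")
    z = (x - mu) / sd
    scale = pd.DataFrame({"snp_id": gm.snp_ids, "mean": mu, "sd": sd})
    return z, scale
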