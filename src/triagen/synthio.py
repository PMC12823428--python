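"""Synthetic multi-cohort generator for case-control genetics + plasma proteomics.

Emulates the statistical structure the downstream stages assume: blockwise-LD
genotypes with a two-variant risk haplotype, a binary mediator (dementia-like)
that transmits part of the haplotype effect onto the binary outcome
(delirium-like), plasma protein traits with cis genetic architecture and
disease effects, demographic covariates, and block-missing protein data.

The generator keeps every generating parameter in a ``truth`` record so that
parameter-recovery tests can compare estimates against the values that
produced the data.

LD model: within each block, haplotypes are drawn from a first-order
autoregressive latent Gaussian (corr = block_r**distance) thresholded at the
allele-frequency quantile, which yields Hardy-Weinberg genotypes with tunable
pairwise r^2.  Each block sits on its own synthetic chromosome with 1-based
positions spaced 10 kb apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

_BP_SPACING = 10_000  # between adjacent variants within a block/chromosome


@dataclass(frozen=True)
class RiskHaplotype:
    """Two-variant risk haplotype (effect alleles of both variants on one
    chromosome copy), with per-copy log-odds effects on mediator and outcome."""

    variants: tuple[int, int]
    logor_mediator: float = 1.1
    logor_outcome: float = 0.131  # direct effect, OR ~ 1.14 per copy


@dataclass(frozen=True)
class GenArchitecture:
    """Genetic architecture shared across cohorts drawn from one population."""

    n_variants: int = 500
    n_blocks: int = 10
    block_r: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    risk_haplotype: RiskHaplotype | None = None
    ancestry_fst_like: float = 0.0  # sd of per-cohort logit-frequency jitter
    freq_seed: int = 7  # base frequencies are an architecture property

    def __post_init__(self):
        if self.n_variants < 2 or self.n_blocks < 1:
            raise ValueError("need at least 2 variants and 1 block")
        if not (0.0 <= self.block_r < 1.0):
            raise ValueError("block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.risk_haplotype is not None:
            i, j = self.risk_haplotype.variants
            if not (0 <= i < self.n_variants and 0 <= j < self.n_variants):
                raise ValueError(
                    f"risk-haplotype variant indices {(i, j)} out of range "
                    f"for {self.n_variants} variants"
                )
            if self.block_of(i) != self.block_of(j):
                raise ValueError("risk-haplotype variants must share a block")

    @property
    def block_size(self) -> int:
        return -(-self.n_variants // self.n_blocks)  # ceil division

    def block_of(self, variant_index: int) -> int:
        return variant_index // self.block_size

    def variant_map(self) -> pd.DataFrame:
        idx = np.arange(self.n_variants)
        block = idx // self.block_size
        within = idx - block * self.block_size
        return pd.DataFrame(
            {
                "id": [f"var{k:05d}" for k in idx],
                "chrom": (block + 1).astype(str),
                "pos": (within + 1) * _BP_SPACING,
                "ea": "A",
                "oa": "G",
            }
        )

    def base_frequencies(self) -> np.ndarray:
        rng = np.random.default_rng(self.freq_seed)
        lo, hi = self.maf_range
        freqs = rng.uniform(lo, hi, size=self.n_variants)
        if self.risk_haplotype is not None:
            i, j = self.risk_haplotype.variants
            freqs[i], freqs[j] = 0.25, 0.35  # common enough for power
        return freqs


@dataclass(frozen=True)
class ProteinArchitecture:
    """Plasma-protein generating model.

    ``cis_effects[k]`` lists (variant index, per-allele effect on the
    standardized level) for protein k; cis variants must fall within
    ±``cis_window_bp`` of the protein's nominal gene.  ``disease_effects[k]``
    is the per-SD log-OR of protein k on the outcome.
    """

    n_proteins: int
    cis_effects: tuple[tuple[tuple[int, float], ...], ...]
    disease_effects: tuple[float, ...]
    gene_positions: tuple[tuple[str, int, int], ...]  # (chrom, start, end)
    missing_rate: float = 0.20
    cis_window_bp: int = 1_000_000

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (
            len(self.cis_effects)
            == len(self.disease_effects)
            == len(self.gene_positions)
            == self.n_proteins
        ):
            raise ValueError("per-protein field lengths must equal n_proteins")

    def validate_cis_windows(self, variants: pd.DataFrame) -> None:
        for k, effs in enumerate(self.cis_effects):
            chrom, start, end = self.gene_positions[k]
            for vi, _ in effs:
                v = variants.iloc[vi]
                if v["chrom"] != chrom or not (
                    start - self.cis_window_bp <= v["pos"] <= end + self.cis_window_bp
                ):
                    raise ValueError(
                        f"protein {k}: cis variant {vi} outside the "
                        f"±{self.cis_window_bp} bp window of its gene"
                    )

    def protein_names(self) -> list[str]:
        return [f"prot{k:04d}" for k in range(self.n_proteins)]

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"protein": name, "chrom": c, "start": s, "end": e}
                for name, (c, s, e) in zip(self.protein_names(), self.gene_positions)
            ]
        )


def default_protein_architecture(
    arch: GenArchitecture,
    n_proteins: int = 40,
    n_causal: int = 5,
    causal_logor: float = 0.3,
    cis_beta: float = 0.35,
    n_cis_per_protein: int = 2,
    n_pleiotropic_variants: int = 0,
    missing_rate: float = 0.20,
    seed: int = 11,
) -> ProteinArchitecture:
    """Assign each protein a gene at a random variant and nearby cis effects.

    The first ``n_causal`` proteins carry a per-SD disease log-OR of
    ``causal_logor``; the rest are null.  ``n_pleiotropic_variants`` variants
    are additionally given cis effects on five proteins each, to exercise the
    pleiotropy filter.
    """
    rng = np.random.default_rng(seed)
    vmap = arch.variant_map()
    cis: list[tuple[tuple[int, float], ...]] = []
    genes: list[tuple[str, int, int]] = []
    for _ in range(n_proteins):
        anchor = int(rng.integers(0, arch.n_variants))
        block = arch.block_of(anchor)
        lo = block * arch.block_size
        hi = min(lo + arch.block_size, arch.n_variants)
        pool = np.arange(lo, hi)
        chosen = rng.choice(pool, size=min(n_cis_per_protein, pool.size), replace=False)
        effs = tuple(
            (int(v), cis_beta * float(rng.choice([-1.0, 1.0]))) for v in chosen
        )
        row = vmap.iloc[anchor]
        genes.append((row["chrom"], int(row["pos"]), int(row["pos"]) + 1_000))
        cis.append(effs)
    if n_pleiotropic_variants:
        for m in range(n_pleiotropic_variants):
            vi = int(rng.integers(0, arch.n_variants))
            vrow = vmap.iloc[vi]
            targets = rng.choice(n_proteins, size=min(5, n_proteins), replace=False)
            for t in targets:
                # pleiotropic variant must still be cis to each target: move
                # the target's gene onto this variant's chromosome, keeping
                # only cis effects that remain inside the window
                genes[t] = (vrow["chrom"], int(vrow["pos"]), int(vrow["pos"]) + 1_000)
                local = tuple(
                    (v, b)
                    for v, b in cis[t]
                    if vmap.iloc[v]["chrom"] == vrow["chrom"]
                )
                cis[t] = local + ((vi, 0.25),)
    disease = tuple(
        causal_logor if k < n_causal else 0.0 for k in range(n_proteins)
    )
    parch = ProteinArchitecture(
        n_proteins=n_proteins,
        cis_effects=tuple(cis),
        disease_effects=disease,
        gene_positions=tuple(genes),
        missing_rate=missing_rate,
    )
    parch.validate_cis_windows(vmap)
    return parch


@dataclass
class CohortBundle:
    """One synthetic cohort: genotypes, phenotypes, proteins and ground truth."""

    genotypes: pd.DataFrame  # samples x variants, dosage 0/1/2, NaN = missing
    variants: pd.DataFrame  # id, chrom, pos, ea, oa, eaf
    phenotypes: pd.DataFrame
    proteins: pd.DataFrame  # samples x proteins, raw levels, NaN = missing
    genes: pd.DataFrame  # protein, chrom, start, end
    truth: dict

    def __post_init__(self):
        if int(self.phenotypes["delirium"].sum()) == 0:
            raise ValueError("cohort contains no cases")
        for _, grp in self.variants.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must increase within chromosome")

    def equals(self, other: "CohortBundle") -> bool:
        try:
            pd.testing.assert_frame_equal(self.genotypes, other.genotypes)
            pd.testing.assert_frame_equal(self.variants, other.variants)
            pd.testing.assert_frame_equal(
                self.phenotypes, other.phenotypes, check_dtype=False
            )
            pd.testing.assert_frame_equal(self.proteins, other.proteins)
            pd.testing.assert_frame_equal(self.genes, other.genes)
        except AssertionError:
            return False
        return True


def simulate_cohort(
    arch: GenArchitecture,
    parch: ProteinArchitecture | None,
    n: int,
    prevalence: float,
    seed: int,
    mediator_prevalence: float = 0.055,
    mediator_logor_outcome: float = 2.0,
    geno_missing_rate: float = 0.0,
) -> CohortBundle:
    """Draw one cohort under logistic outcome and mediator models.

    The outcome intercept is solved so the expected case fraction equals
    ``prevalence`` given the realized linear predictors; covariate effects
    (age, sex, BMI) are fixed package defaults recorded in the truth record.
    """
    if n < 100:
        raise ValueError(f"n must be >= 100, got {n}")
    if not (0.0 < prevalence < 0.5):
        raise ValueError(f"prevalence must lie in (0, 0.5), got {prevalence}")

    ss = np.random.SeedSequence(seed)
    rng_geno, rng_cov, rng_med, rng_out, rng_prot, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    # --- allele frequencies, with optional ancestry-like jitter
    freqs = arch.base_frequencies()
    if arch.ancestry_fst_like > 0:
        logit = np.log(freqs / (1 - freqs))
        logit += rng_geno.normal(0.0, arch.ancestry_fst_like, size=freqs.size)
        freqs = expit(logit)
    freqs = np.clip(freqs, 1e-4, 1 - 1e-4)

    # --- haplotypes blockwise (2 per individual), thresholded AR(1) Gaussian
    haps = np.empty((2 * n, arch.n_variants), dtype=np.int8)
    bs = arch.block_size
    for b in range(arch.n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, arch.n_variants)
        m = hi - lo
        if m <= 0:
            continue
        if arch.block_r > 0:
            corr = arch.block_r ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            L = np.linalg.cholesky(corr)
            z = rng_geno.standard_normal((2 * n, m)) @ L.T
        else:
            z = rng_geno.standard_normal((2 * n, m))
        haps[:, lo:hi] = z < ndtri(freqs[lo:hi])
    dosage = (haps[0::2] + haps[1::2]).astype(float)

    # --- risk haplotype count (copies carrying both effect alleles)
    if arch.risk_haplotype is not None:
        i, j = arch.risk_haplotype.variants
        carrier = ((haps[:, i] == 1) & (haps[:, j] == 1)).astype(np.int8)
        hap_count = (carrier[0::2] + carrier[1::2]).astype(float)
        b_med = arch.risk_haplotype.logor_mediator
        b_dir = arch.risk_haplotype.logor_outcome
    else:
        hap_count = np.zeros(n)
        b_med = b_dir = 0.0

    # --- covariates
    age = rng_cov.normal(60.0, 8.0, size=n)
    sex = rng_cov.integers(0, 2, size=n).astype(float)
    bmi = rng_cov.normal(27.0, 4.0, size=n)

    cov_med = 0.08 * (age - 60.0) + 0.05 * sex
    cov_out = 0.05 * (age - 60.0) + 0.10 * sex + 0.01 * (bmi - 27.0)

    # --- mediator (dementia-like), prevalence-calibrated intercept
    lp_med = b_med * hap_count + cov_med
    a0 = _solve_intercept(lp_med, mediator_prevalence)
    mediator = (rng_med.random(n) < expit(a0 + lp_med)).astype(int)

    # --- proteins: cis genetics + noise, standardized true scale
    if parch is not None and parch.n_proteins > 0:
        prot_true = np.empty((n, parch.n_proteins))
        std_geno = (dosage - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))
        for k, effs in enumerate(parch.cis_effects):
            g = np.zeros(n)
            var_g = 0.0
            for vi, beta in effs:
                g += beta * std_geno[:, vi]
                var_g += beta * beta
            noise_sd = np.sqrt(max(1.0 - var_g, 0.1))
            prot_true[:, k] = g + rng_prot.normal(0.0, noise_sd, size=n)
        disease = np.asarray(parch.disease_effects)
        lp_prot = prot_true @ disease
    else:
        prot_true = np.zeros((n, 0))
        lp_prot = np.zeros(n)

    # --- outcome
    lp_out = b_dir * hap_count + mediator_logor_outcome * mediator + cov_out + lp_prot
    c0 = _solve_intercept(lp_out, prevalence)
    outcome = (rng_out.random(n) < expit(c0 + lp_out)).astype(int)

    # --- follow-up and incident definition (>1 year post-baseline)
    follow = rng_cov.uniform(1.0, 16.0, size=n)
    onset = np.where(outcome == 1, rng_cov.uniform(0.0, 1.0, size=n) * follow, np.nan)
    incident = ((outcome == 1) & (onset > 1.0)).astype(int)

    # --- missingness
    if geno_missing_rate > 0:
        mask = rng_miss.random(dosage.shape) < geno_missing_rate
        dosage[mask] = np.nan
    prot_raw = prot_true.copy()
    if parch is not None and parch.missing_rate > 0 and parch.n_proteins > 0:
        pmask = rng_miss.random(prot_raw.shape) < parch.missing_rate
        prot_raw[pmask] = np.nan

    samples = [f"s{k:06d}" for k in range(n)]
    vmap = arch.variant_map()
    vmap["eaf"] = freqs
    geno_df = pd.DataFrame(dosage, index=samples, columns=vmap["id"].tolist())
    pheno = pd.DataFrame(
        {
            "sample_id": samples,
            "delirium": outcome,
            "dementia": mediator,
            "age": age,
            "sex": sex.astype(int),
            "bmi": bmi,
            "follow_years": follow,
            "hap_count": hap_count.astype(int),
            "incident": incident,
        }
    )
    pnames = parch.protein_names() if parch is not None else []
    prot_df = pd.DataFrame(prot_raw, index=samples, columns=pnames)
    genes = (
        parch.gene_table()
        if parch is not None
        else pd.DataFrame(columns=["protein", "chrom", "start", "end"])
    )

    truth = {
        "seed": seed,
        "n": n,
        "prevalence": prevalence,
        "mediator_prevalence": mediator_prevalence,
        "mediator_logor_outcome": mediator_logor_outcome,
        "hap_logor_mediator": b_med,
        "hap_logor_outcome_direct": b_dir,
        "outcome_intercept": c0,
        "mediator_intercept": a0,
        "freqs": freqs.tolist(),
        "covar_effects_outcome": {"age": 0.05, "sex": 0.10, "bmi": 0.01},
        "covar_effects_mediator": {"age": 0.08, "sex": 0.05},
        "protein_disease_effects": (
            list(parch.disease_effects) if parch is not None else []
        ),
        "protein_cis_effects": (
            [[[int(v), float(b)] for v, b in effs] for effs in parch.cis_effects]
            if parch is not None
            else []
        ),
        "arch": {
            "n_variants": arch.n_variants,
            "n_blocks": arch.n_blocks,
            "block_r": arch.block_r,
            "maf_range": list(arch.maf_range),
            "ancestry_fst_like": arch.ancestry_fst_like,
            "freq_seed": arch.freq_seed,
            "risk_haplotype": (
                {
                    "variants": list(arch.risk_haplotype.variants),
                    "logor_mediator": arch.risk_haplotype.logor_mediator,
                    "logor_outcome": arch.risk_haplotype.logor_outcome,
                }
                if arch.risk_haplotype
                else None
            ),
        },
    }
    return CohortBundle(geno_df, vmap, pheno, prot_df, genes, truth)


def sensitivity_covariates(phenotypes: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Extended confounder set for the sensitivity mediation model.

    Emulates three shared dementia/delirium risk factors: a general cognitive
    ability composite (first principal component of four correlated test
    scores, two of them log/log1p transformed before the PCA, lower with age
    and with the mediator), a socioeconomic deprivation decile, and a
    comorbidity burden index (weighted count of chronic conditions, rising
    with age).  Returns columns ``cognition_pc1``, ``deprivation_decile``,
    ``comorbidity_index`` aligned to the phenotype rows.
    """
    rng = np.random.default_rng(seed)
    n = len(phenotypes)
    age = phenotypes["age"].to_numpy(dtype=float)
    mediator = phenotypes["dementia"].to_numpy(dtype=float)

    ability = -0.03 * (age - 60.0) - 0.8 * mediator + rng.normal(0, 1, n)
    fluid = 6.0 + 1.5 * ability + rng.normal(0, 1, n)
    numeric = 7.0 + 1.2 * ability + rng.normal(0, 1.2, n)
    # reaction time and visual-memory errors: positive, lower ability = slower
    reaction = np.exp(6.2 - 0.10 * ability + rng.normal(0, 0.15, n))
    visual = rng.poisson(np.exp(1.2 - 0.25 * ability)).astype(float)

    tests = np.column_stack(
        [fluid, numeric, np.log(reaction), np.log1p(visual)]
    )
    tests = (tests - tests.mean(axis=0)) / tests.std(axis=0)
    cov = np.cov(tests.T)
    vals, vecs = np.linalg.eigh(cov)
    pc1 = tests @ vecs[:, -1]
    if np.corrcoef(pc1, fluid)[0, 1] < 0:  # orient: higher = better cognition
        pc1 = -pc1

    deprivation = np.clip(
        np.ceil(10 * rng.beta(2.0, 2.0, n)).astype(int), 1, 10
    ).astype(float)
    comorbidity = rng.poisson(
        np.exp(-1.5 + 0.04 * (age - 60.0) + 0.5 * mediator)
    ).astype(float)

    return pd.DataFrame(
        {
            "cognition_pc1": pc1,
            "deprivation_decile": deprivation,
            "comorbidity_index": comorbidity,
        },
        index=phenotypes.index,
    )


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + lp)) == target."""

    def f(c):
        return float(np.mean(expit(c + lp))) - target

    return brentq(f, -40.0, 40.0, xtol=1e-12)


# ---------------------------------------------------------------------------
# persistence


def write_bundle(bundle: CohortBundle, directory: str | Path) -> dict:
    """Write a bundle as plain-text tables; returns (and writes) a manifest.

    Layout: genotypes.tsv (variant_id + one column per sample), variants.tsv,
    phenotypes.tsv, proteins.tsv (samples x proteins, NA for missing),
    genes.tsv, truth.json, manifest.json.  Round-trips via ``read_bundle``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    geno_t = bundle.genotypes.T
    geno_t.index.name = "variant_id"
    geno_t.to_csv(d / "genotypes.tsv", sep="\t", na_rep="NA", float_format="%.10g")
    bundle.variants.to_csv(d / "variants.tsv", sep="\t", index=False)
    bundle.phenotypes.to_csv(d / "phenotypes.tsv", sep="\t", index=False)
    has_proteins = bundle.proteins.shape[1] > 0
    prot = bundle.proteins.copy()
    prot.index.name = "sample_id"
    prot.to_csv(d / "proteins.tsv", sep="\t", na_rep="NA", float_format="%.10g")
    bundle.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    (d / "truth.json").write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))

    manifest = {
        "n_samples": int(bundle.genotypes.shape[0]),
        "n_variants": int(bundle.genotypes.shape[1]),
        "n_proteins": int(bundle.proteins.shape[1]),
        "proteomics_present": bool(has_proteins),
        "files": [
            "genotypes.tsv",
            "variants.tsv",
            "phenotypes.tsv",
            "proteins.tsv",
            "genes.tsv",
            "truth.json",
        ],
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_bundle(directory: str | Path) -> CohortBundle:
    d = Path(directory)
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col=0, na_values="NA").T
    geno.index.name = None
    geno.columns.name = None
    variants = pd.read_csv(d / "variants.tsv", sep="\t", dtype={"chrom": str})
    pheno = pd.read_csv(d / "phenotypes.tsv", sep="\t")
    prot = pd.read_csv(d / "proteins.tsv", sep="\t", index_col=0, na_values="NA")
    prot.index.name = None
    genes = pd.read_csv(d / "genes.tsv", sep="\t", dtype={"chrom": str})
    truth = json.loads((d / "truth.json").read_text())
    return CohortBundle(geno, variants, pheno, prot, genes, truth)


def write_vcf(bundle: CohortBundle, path: str | Path) -> None:
    """Write genotypes as a minimal VCFv4.2 with GT and DS fields."""
    path = Path(path)
    samples = list(bundle.genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">',
    ]
    for chrom in bundle.variants["chrom"].unique():
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    geno = bundle.genotypes.to_numpy()
    for vi, row in bundle.variants.iterrows():
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            str(row["id"]),
            str(row["oa"]),  # REF = other allele, ALT = effect allele
            str(row["ea"]),
            ".",
            "PASS",
            ".",
            "GT:DS",
        ]
        col = geno[:, vi]
        for v in col:
            if np.isnan(v):
                fields.append("./.:.")
            else:
                fields.append(f"{gt_map[float(v)]}:{v:g}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_vcf_dosages(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF written by :func:`write_vcf`; returns (genotypes, variants)."""
    samples: list[str] = []
    var_rows = []
    dosages = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            var_rows.append(
                {
                    "id": parts[2],
                    "chrom": parts[0],
                    "pos": int(parts[1]),
                    "ea": parts[4],
                    "oa": parts[3],
                }
            )
            fmt = parts[8].split(":")
            ds_i = fmt.index("DS")
            row = []
            for cell in parts[9:]:
                ds = cell.split(":")[ds_i]
                row.append(np.nan if ds == "." else float(ds))
            dosages.append(row)
    variants = pd.DataFrame(var_rows)
    geno = pd.DataFrame(
        np.asarray(dosages).T, index=samples, columns=variants["id"].tolist()
    )
    return geno, variants
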