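"""From classified read counts to bias-corrected fractions, relative
abundances and standardized quantities.

Notation, per amplicon and sample: gamma_hs is the observed fraction of
target-species reads; gamma_hs_c is that fraction after correcting the
multiplicative procedural (amplification/purification) bias against one or
more reference samples of known composition; RA_H/P is the relative
abundance of the target sequence against the per-genome copy representation
of its competitor in the spike-in genome; StdQt is RA_H/P divided by a
per-sample standard value (the mean RA_H/P of a chosen standard set), which
puts different sequences on one comparable scale.

Bias model and correction: a per-amplicon factor beta multiplies the
target:competitor odds, so a reference sample with known target fraction p
and observed fraction g_ref determines per-species weights
``wA = p/g_ref`` and ``wB = (1-p)/(1-g_ref)``; the corrected fraction of an
observation g is ``g*wA / (g*wA + (1-g)*wB)``.  With p = 1/2 this reduces
to the classical equi-molar-reference correction.  Several reference
samples are combined by averaging the per-species weights arithmetically;
when the bias is constant across samples and the reference compositions are
exact this aggregation recovers the true odds exactly, because every
reference contributes weights wA_j = c_j/beta and wB_j = c_j with a shared
c_j, leaving the ratio mean(wA)/mean(wB) = 1/beta.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import CopyModel


# ---------------------------------------------------------------------------
# fractions and QC

def compute_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Observed target-species fraction per (sample, amplicon).

    Adds ``depth`` and ``gamma_hs``; amplicons with zero reads get a missing
    fraction rather than an error.
    """
    df = counts.copy()
    df["depth"] = df["n_target"] + df["n_competitor"]
    with np.errstate(invalid="ignore"):
        df["gamma_hs"] = np.where(
            df["depth"] > 0, df["n_target"] / df["depth"].replace(0, np.nan), np.nan
        )
    return df


def qc_filter(
    fractions: pd.DataFrame,
    min_mean_reads: float = 200,
    purity_flags: pd.DataFrame | Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Mark amplicons failing depth or purity criteria.

    An amplicon fails when its mean read depth across the table's samples is
    strictly below ``min_mean_reads`` (a mean of exactly 200 passes) or when
    it was flagged impure in the pure samples.  Adds ``qc_pass`` and
    ``qc_reason`` columns (reason shared by all rows of an amplicon).
    """
    mean_depth = fractions.groupby("amplicon_id")["depth"].mean()
    if isinstance(purity_flags, pd.DataFrame):
        impure = purity_flags.set_index("amplicon_id")["impure"]
    elif purity_flags is not None:
        impure = pd.Series(dict(purity_flags))
    else:
        impure = pd.Series(dtype="boolean")
    reasons = {}
    for amp in mean_depth.index:
        r = []
        if mean_depth[amp] < min_mean_reads:
            r.append("low_depth")
        flag = impure.get(amp, False)
        if not pd.isna(flag) and bool(flag):
            r.append("impure")
        reasons[amp] = ";".join(r)
    df = fractions.copy()
    df["qc_reason"] = df["amplicon_id"].map(reasons).fillna("")
    df["qc_pass"] = df["qc_reason"] == ""
    return df


def estimate_reference_fractions(fractions: pd.DataFrame) -> pd.Series:
    """Self-estimated composition of each reference sample.

    Assuming the per-amplicon biases average out across the panel, the
    unweighted mean of the *raw* gamma_hs over QC-passing amplicons of a
    sample estimates that sample's true target-species fraction.
    """
    sub = fractions[fractions["qc_pass"]] if "qc_pass" in fractions else fractions
    sub = sub.dropna(subset=["gamma_hs"])
    if sub.empty:
        raise ValueError("no QC-passing amplicons to estimate reference fractions from")
    p = sub.groupby("sample_id")["gamma_hs"].mean()
    missing = set(fractions["sample_id"].unique()) - set(p.index)
    if missing:
        raise ValueError(f"no passing amplicons for samples {sorted(missing)}")
    return p.rename("p_ref")


# ---------------------------------------------------------------------------
# bias correction

def correct_bias_single(gamma, gamma_ref: float, p_ref: float):
    """Correct an observed fraction against one reference sample of known
    composition ``p_ref`` and observed fraction ``gamma_ref``."""
    gamma_ref = float(gamma_ref)
    p_ref = float(p_ref)
    if not 0.0 < gamma_ref < 1.0:
        raise ValueError("reference observed fraction must lie strictly in (0,1)")
    if not 0.0 < p_ref < 1.0:
        raise ValueError("reference composition must lie strictly in (0,1)")
    w_a = p_ref / gamma_ref
    w_b = (1.0 - p_ref) / (1.0 - gamma_ref)
    gamma = np.asarray(gamma, dtype=float)
    num = gamma * w_a
    out = num / (num + (1.0 - gamma) * w_b)
    return float(out) if out.ndim == 0 else out


def correct_bias_multi(
    gamma,
    references: Sequence[tuple[float, float]],
    aggregate: str = "weights",
):
    """Correct against multiple reference samples.

    ``references`` is a sequence of (observed fraction, known composition)
    per reference.  The default aggregation averages the per-species weights
    arithmetically across usable references (observed fraction strictly
    inside (0,1)); ``aggregate="corrected"`` instead averages the
    single-reference corrected values.  A single reference reduces exactly
    to :func:`correct_bias_single`.
    """
    usable = [(g, p) for g, p in references if 0.0 < g < 1.0]
    if len(usable) < len(references):
        warnings.warn(
            "skipping reference samples with observed fraction 0 or 1 (bias unobservable)",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no usable reference samples")
    gamma = np.asarray(gamma, dtype=float)
    if aggregate == "weights":
        w_a = float(np.mean([p / g for g, p in usable]))
        w_b = float(np.mean([(1.0 - p) / (1.0 - g) for g, p in usable]))
        num = gamma * w_a
        out = num / (num + (1.0 - gamma) * w_b)
    elif aggregate == "corrected":
        out = np.mean(
            [correct_bias_single(gamma, g, p) for g, p in usable], axis=0
        )
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def _weight_frames(
    piv: pd.DataFrame, p_ref: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-(amplicon, reference sample) weights wA, wB and a usability mask."""
    p = p_ref.reindex(piv.columns)
    usable = piv.notna() & (piv > 0) & (piv < 1) & (p > 0) & (p < 1)
    w_a = pd.DataFrame(
        p.values[None, :] / piv.values, index=piv.index, columns=piv.columns
    ).where(usable)
    w_b = pd.DataFrame(
        (1.0 - p.values)[None, :] / (1.0 - piv.values),
        index=piv.index,
        columns=piv.columns,
    ).where(usable)
    return w_a, w_b, usable


def correct_gdna_set(
    fractions: pd.DataFrame, p_ref: pd.Series | None = None
) -> pd.DataFrame:
    """Leave-one-out multi-reference correction of a gDNA mixture series.

    Every sample is corrected, per amplicon, against all *other* samples of
    the set (a sample never serves as its own reference), with reference
    compositions self-estimated from raw fractions unless supplied.  Only
    QC-passing amplicons receive a corrected value.  Adds ``gamma_hs_c``.
    """
    if fractions["sample_id"].nunique() < 2:
        raise ValueError("leave-one-out correction needs at least two samples")
    sub = fractions[fractions["qc_pass"]] if "qc_pass" in fractions else fractions
    piv = sub.pivot(index="amplicon_id", columns="sample_id", values="gamma_hs")
    if p_ref is None:
        p_ref = estimate_reference_fractions(sub)
    w_a, w_b, usable = _weight_frames(piv, p_ref)
    tot_a, tot_b, cnt = w_a.sum(axis=1), w_b.sum(axis=1), usable.sum(axis=1)
    corrected = {}
    for sample in piv.columns:
        n_ref = cnt - usable[sample].astype(int)
        mean_a = (tot_a - w_a[sample].fillna(0)) / n_ref.where(n_ref > 0)
        mean_b = (tot_b - w_b[sample].fillna(0)) / n_ref.where(n_ref > 0)
        g = piv[sample]
        num = g * mean_a
        corrected[sample] = num / (num + (1.0 - g) * mean_b)
    corr = pd.DataFrame(corrected).stack().rename("gamma_hs_c")
    corr.index.names = ["amplicon_id", "sample_id"]
    out = fractions.merge(
        corr.reset_index(), on=["sample_id", "amplicon_id"], how="left"
    )
    return out


def correct_cdna_set(
    cdna_fractions: pd.DataFrame,
    gdna_fractions: pd.DataFrame,
    p_ref: pd.Series | None = None,
) -> pd.DataFrame:
    """Correct cDNA fractions against the gDNA mixtures of the same
    replication set.

    Per amplicon, all gDNA samples with a usable observed fraction act as
    references; amplicons without any corresponding gDNA data keep a missing
    corrected value with reason ``no_reference``.  Adds ``gamma_hs_c``,
    ``n_correction_refs`` and ``correction_reason``.
    """
    gsub = gdna_fractions[gdna_fractions["qc_pass"]] if "qc_pass" in gdna_fractions else gdna_fractions
    piv = gsub.pivot(index="amplicon_id", columns="sample_id", values="gamma_hs")
    if p_ref is None:
        p_ref = estimate_reference_fractions(gsub)
    w_a, w_b, usable = _weight_frames(piv, p_ref)
    mean_a = w_a.mean(axis=1)
    mean_b = w_b.mean(axis=1)
    n_refs = usable.sum(axis=1)

    out = cdna_fractions.copy()
    out["n_correction_refs"] = (
        out["amplicon_id"].map(n_refs).fillna(0).astype(int)
    )
    ma = out["amplicon_id"].map(mean_a)
    mb = out["amplicon_id"].map(mean_b)
    g = out["gamma_hs"]
    num = g * ma
    out["gamma_hs_c"] = (num / (num + (1.0 - g) * mb)).where(out["n_correction_refs"] > 0)
    out["correction_reason"] = np.where(
        out["n_correction_refs"] > 0, "", "no_reference"
    )
    return out


# ---------------------------------------------------------------------------
# relative abundance and standardization

def to_relative_abundance(
    df: pd.DataFrame, copy_model: CopyModel, gamma_col: str = "gamma_hs_c"
) -> pd.DataFrame:
    """Convert corrected fractions to relative abundances RA_H/P.

    ``RA = gamma/(1-gamma) * competitor_copies/2``: the corrected odds of
    target to competitor reads, rescaled so that the competitor side counts
    per-genome copies (X-linked loci of a male competitor carry one copy,
    not two).  A fraction of exactly 1 (no competitor reads) has no finite
    odds and propagates as missing.
    """
    out = df.copy()
    g = out[gamma_col]
    cc = out["amplicon_id"].map(copy_model.competitor_copies)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = g / (1.0 - g) * cc / 2.0
    out["ra_hp"] = ra.where((g < 1.0) & g.notna())
    return out


def standardize(
    df: pd.DataFrame,
    standard: str | Sequence[str] = "autosomal",
    copy_model: CopyModel | None = None,
) -> pd.DataFrame:
    """Scale each sample's relative abundances by its standard value.

    The standard value is the mean RA_H/P over the standard set —
    ``"autosomal"`` (requires a copy model), ``"all"``, or an explicit
    amplicon list — restricted to QC-passing amplicons with a finite RA.
    By construction the mean StdQt over the standard set is 1 per sample.
    """
    out = df.copy()
    if isinstance(standard, str):
        if standard == "autosomal":
            if copy_model is None:
                raise ValueError("autosomal standard requires a copy model")
            in_std = out["amplicon_id"].map(
                lambda a: copy_model.class_of(a) == "autosomal"
            )
        elif standard == "all":
            in_std = pd.Series(True, index=out.index)
        else:
            raise ValueError(f"unknown standard {standard!r}")
    else:
        member = set(standard)
        if not member:
            raise ValueError("empty standard set")
        in_std = out["amplicon_id"].isin(member)
    eligible = in_std & out["ra_hp"].notna()
    if "qc_pass" in out:
        eligible &= out["qc_pass"]
    std = out[eligible].groupby("sample_id")["ra_hp"].mean()
    if std.empty or (std <= 0).any() or std.isna().any():
        raise ValueError("standard set mean is zero, negative or undefined")
    out["standard_value"] = out["sample_id"].map(std)
    out["stdqt"] = out["ra_hp"] / out["standard_value"]
    return out


def average_stdqt(quant: pd.DataFrame) -> pd.Series:
    """Per-amplicon mean StdQt over the samples where it is defined."""
    return quant.groupby("amplicon_id")["stdqt"].mean().rename("mean_stdqt")


# ---------------------------------------------------------------------------
# summary statistics

def rmsd(values, expected) -> float:
    """Root mean square deviation between paired vectors (missing pairs
    skipped)."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(expected, dtype=float)
    if v.shape != e.shape:
        raise ValueError("values and expected must have the same shape")
    ok = ~(np.isnan(v) | np.isnan(e))
    if not ok.any():
        return float("nan")
    return float(np.sqrt(np.mean((v[ok] - e[ok]) ** 2)))


def cv(values) -> float:
    """Coefficient of variation: sample standard deviation (n-1) over the
    mean.  cv({1,2}) = 0.471, the two-fold-difference landmark."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def multilocus_summary(
    quant: pd.DataFrame, gene_map: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consistency of quantitation across multiple loci of single genes.

    Returns ``(per_gene_sample, per_gene)``: the CV of locus StdQts within
    each (gene, sample), and a per-gene table with the mean CV over samples
    plus the ratio of the two loci's averaged StdQts (first/second locus by
    amplicon id) for genes measured at exactly two or more loci.  Genes with
    fewer than two quantified loci are excluded.
    """
    q = quant.dropna(subset=["stdqt"]).copy()
    q["gene_id"] = q["amplicon_id"].map(dict(gene_map))
    q = q.dropna(subset=["gene_id"])
    rows = []
    for (gene, sample), block in q.groupby(["gene_id", "sample_id"]):
        if block["amplicon_id"].nunique() < 2:
            continue
        rows.append(
            {"gene_id": gene, "sample_id": sample, "locus_cv": cv(block["stdqt"])}
        )
    per_gene_sample = pd.DataFrame(rows, columns=["gene_id", "sample_id", "locus_cv"])
    gene_rows = []
    for gene, block in q.groupby("gene_id"):
        loci = sorted(block["amplicon_id"].unique())
        if len(loci) < 2:
            continue
        means = block.groupby("amplicon_id")["stdqt"].mean()
        sub = per_gene_sample[per_gene_sample["gene_id"] == gene]
        gene_rows.append(
            {
                "gene_id": gene,
                "n_loci": len(loci),
                "mean_locus_cv": sub["locus_cv"].mean() if not sub.empty else np.nan,
                "locus_ratio": means[loci[0]] / means[loci[1]]
                if means[loci[1]] != 0
                else np.nan,
            }
        )
    per_gene = pd.DataFrame(
        gene_rows, columns=["gene_id", "n_loci", "mean_locus_cv", "locus_ratio"]
    )
    return per_gene_sample, per_gene


def strength_bias_test(
    mean_gamma: pd.Series, strength_class: pd.Series | Mapping[str, str]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test of whether amplicons whose
    target variant forms strong (G/C) hydrogen bonds show systematically
    different observed fractions than weak-variant (A/T) amplicons.

    Returns (U statistic for the S class, p-value).
    """
    cls = pd.Series(dict(strength_class)) if not isinstance(strength_class, pd.Series) else strength_class
    aligned = pd.DataFrame({"gamma": mean_gamma, "cls": cls}).dropna()
    s = aligned.loc[aligned["cls"] == "S", "gamma"]
    w = aligned.loc[aligned["cls"] == "W", "gamma"]
    if s.empty or w.empty:
        raise ValueError("both strength classes must be non-empty")
    res = sps.mannwhitneyu(s, w, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def spikein_copy_estimate(
    mass_ng: float, haploid_mass_pg: float = 3.3, ra: float | None = None
) -> float:
    """Copies of an autosomal unique sequence in ``mass_ng`` of spike-in
    gDNA (one copy per 3.3 pg haploid genome equivalent: ~303 per ng), or
    the corresponding target-sequence copies when a relative abundance is
    given."""
    if mass_ng < 0:
        raise ValueError("mass must be >= 0")
    copies = mass_ng * 1000.0 / haploid_mass_pg
    return copies * ra if ra is not None else copies


def cross_platform_bias_correct(
    stdqt_ref_sample_a: pd.Series,
    stdqt_other_sample_a: pd.Series,
    stdqt_other_sample_b: pd.Series,
) -> pd.Series:
    """Transfer gene-by-gene systematic biases between two quantitation
    platforms: the bias of the other platform is measured on sample A
    against the reference platform and divided out of the other platform's
    sample B.  Keys with zero or missing reference values are dropped.
    """
    bias = stdqt_other_sample_a / stdqt_ref_sample_a
    bias = bias.replace([np.inf, -np.inf], np.nan).dropna()
    bias = bias[bias != 0]
    out = (stdqt_other_sample_b / bias).dropna()
    return out.rename("stdqt_corrected")


def measurement_window(ra_values, min_ra: float = 0.05) -> dict:
    """Dynamic range of direct inter-sequence comparison: the fold ratio of
    the largest to the smallest relative abundance above ``min_ra``."""
    v = np.asarray(ra_values, dtype=float)
    v = v[~np.isnan(v)]
    v = v[v > min_ra]
    if v.size == 0:
        return {"ra_max": float("nan"), "ra_min": float("nan"), "fold": float("nan"), "n": 0}
    return {
        "ra_max": float(v.max()),
        "ra_min": float(v.min()),
        "fold": float(v.max() / v.min()),
        "n": int(v.size),
    }
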