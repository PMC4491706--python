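"""Turn-key simulated benchmark studies.

These run the complete counts-level analysis under the canonical study
conditions — a gDNA mixture series quantified by leave-one-out
multi-reference correction, and a cDNA triplicate spike-in series
bias-corrected against a gDNA reference set — and report the accuracy and
reproducibility summaries of the method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import quantify as q
from . import simulate
from .models import BiasModel, CopyModel


def gdna_accuracy_study(
    seed: int,
    n_amplicons: int = 350,
    frac_x_linked: float = 0.05,
    fractions: tuple = (0.1, 0.3, 0.5, 0.7, 0.9),
    bias_sd_log: float = 0.5,
    mean_depth: float = 5000.0,
    depth_sd_log: float = 0.5,
    human_sex: str = "female",
) -> dict:
    """Accuracy of standardized quantities on simulated gDNA mixtures.

    Simulates the mixture series with per-amplicon log-normal biases held
    constant across samples, runs leave-one-out multi-reference correction
    with self-estimated reference fractions, converts to relative
    abundances, standardizes to the autosomal mean, averages StdQt per
    amplicon over the samples and reports the RMSD against the expected
    values plus per-sample dispersion summaries.
    """
    seed = int(seed) % 2**31
    specs, pairs = simulate.make_homolog_pairs(
        n_amplicons, frac_x_linked=frac_x_linked, seed=seed
    )
    amps = [p.amplicon_id for p in pairs]
    bias = BiasModel.lognormal(
        amps,
        sd_log=bias_sd_log,
        mean_depth=mean_depth,
        depth_sd_log=depth_sd_log,
        seed=seed + 1,
    )
    designs = simulate.make_gdna_designs(fractions)
    counts, truth = simulate.simulate_gdna_counts(
        pairs, designs, bias, human_sex=human_sex, seed=seed + 2
    )
    fractions_tbl = q.qc_filter(q.compute_fractions(counts))
    fractions_tbl = q.correct_gdna_set(fractions_tbl)
    copy_model = CopyModel.from_pairs(pairs, target_sex=human_sex)
    quant = q.standardize(
        q.to_relative_abundance(fractions_tbl, copy_model),
        standard="autosomal",
        copy_model=copy_model,
    )
    averaged = q.average_stdqt(quant)
    expected = simulate.expected_stdqt_gdna(pairs, copy_model).reindex(averaged.index)
    per_sample_cv_raw = {}
    per_sample_cv_corrected = {}
    for sample, block in fractions_tbl.groupby("sample_id"):
        per_sample_cv_raw[sample] = q.cv(block["gamma_hs"])
        per_sample_cv_corrected[sample] = q.cv(block["gamma_hs_c"])
    return {
        "n_amplicons": len(pairs),
        "n_samples": len(designs),
        "rmsd_avg_stdqt": q.rmsd(averaged, expected),
        "cv_gamma_corrected": per_sample_cv_corrected,
        "cv_gamma_raw": per_sample_cv_raw,
        "max_cv_gamma_corrected": max(per_sample_cv_corrected.values()),
        "quant": quant,
        "averaged_stdqt": averaged,
        "expected_stdqt": expected,
        "truth": truth,
    }


def cdna_replicate_study(
    seed: int,
    n_amplicons: int = 350,
    frac_x_linked: float = 0.05,
    mean_ra_levels: tuple = (5.0, 2.5, 1.0),
    bias_sd_log: float = 0.5,
    mean_depth: float = 5000.0,
    depth_sd_log: float = 0.5,
    expression_sd_log: float = 1.2,
    gdna_fractions: tuple = (0.1, 0.3, 0.5, 0.7, 0.9),
    min_ra: float = 0.05,
    group: str = "I",
) -> dict:
    """Reproducibility of StdQts across graded spike-in replicates.

    One cell line's cDNA is simulated three times with spike-in masses set
    so the sample-mean relative abundances sit near the requested levels;
    the same constant per-amplicon biases also generate a gDNA mixture
    series used as the bias reference.  For every amplicon inside the
    direct-comparison window (RA above ``min_ra`` in all samples) the CV of
    its per-sample StdQts measures agreement across spike-in levels.
    """
    seed = int(seed) % 2**31
    specs, pairs = simulate.make_homolog_pairs(
        n_amplicons, frac_x_linked=frac_x_linked, seed=seed
    )
    amps = [p.amplicon_id for p in pairs]
    bias = BiasModel.lognormal(
        amps,
        sd_log=bias_sd_log,
        mean_depth=mean_depth,
        depth_sd_log=depth_sd_log,
        seed=seed + 1,
    )
    gdesigns = simulate.make_gdna_designs(gdna_fractions)
    gcounts, _ = simulate.simulate_gdna_counts(pairs, gdesigns, bias, seed=seed + 2)
    gfr = q.qc_filter(q.compute_fractions(gcounts))

    expression = simulate.sample_expression_profile(
        amps, sd_log=expression_sd_log, seed=seed + 3
    )
    base_mass = simulate.spike_mass_for_mean_ra(expression, max(mean_ra_levels))
    masses = [base_mass * max(mean_ra_levels) / level for level in mean_ra_levels]
    designs = simulate.make_cdna_designs(expression, masses, group=group)
    counts, truth = simulate.simulate_cdna_counts(pairs, designs, bias, seed=seed + 4)
    cfr = q.qc_filter(q.compute_fractions(counts))
    cfr = q.correct_cdna_set(cfr, gfr)
    copy_model = CopyModel.from_pairs(pairs)
    quant = q.standardize(
        q.to_relative_abundance(cfr, copy_model), standard="all"
    )
    ra = quant.pivot(index="amplicon_id", columns="sample_id", values="ra_hp")
    in_window = ra.notna().all(axis=1) & (ra > min_ra).all(axis=1)
    stdqt = quant.pivot(index="amplicon_id", columns="sample_id", values="stdqt")
    cvs = stdqt.loc[in_window].apply(q.cv, axis=1)
    mean_ra = quant.groupby("sample_id")["ra_hp"].mean()
    return {
        "n_amplicons": len(pairs),
        "n_in_window": int(in_window.sum()),
        "sample_mean_ra": mean_ra.to_dict(),
        "stdqt_cv": cvs,
        "max_stdqt_cv": float(cvs.max()),
        "mean_stdqt_cv": float(cvs.mean()),
        "quant": quant,
        "expression": expression,
        "truth": truth,
    }
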