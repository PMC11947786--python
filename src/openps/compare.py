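"""Cross-mode and cross-instrument comparison, and pipeline orchestration.

Compares protein calls between the strict monoisotopic window and the
wide (-3/+5 Da) window, and between the two instrument archetypes:
Venn overlaps of accepted gene symbols, ordinary least-squares
regression of log10 peptide observation frequencies over shared gene
symbols, and the type-II-error rate implied by restricting a wide-window
result to the monoisotopic mass.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .deltamass import delta_histogram, detect_integer_peaks, envelope_agreement
from .insilico import delta_envelope, isotope_envelope, peptide_composition
from .io_formats import write_results_table
from .protein_stats import (
    PROTEIN_FIELDS,
    ProteinCallConfig,
    accepted_gene_symbols,
    call_proteins,
)
from .search import (
    PSM_FIELDS,
    SearchConfig,
    build_index,
    filter_monoisotopic,
    search_run,
)
from .synthetic_data import (
    SimConfig,
    generate_random_msms,
    make_library,
    simulate_blank,
    simulate_run,
)


def venn(symbols_a, symbols_b, symbols_c=None) -> dict:
    """Exact overlap counts for 2 or 3 sets of gene symbols."""
    a, b = set(symbols_a), set(symbols_b)
    if symbols_c is None:
        return {
            "a_only": len(a - b),
            "b_only": len(b - a),
            "both": len(a & b),
        }
    c = set(symbols_c)
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
    }


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    residual_se: float
    n: int


def log_count_regression(counts_a: dict, counts_b: dict) -> RegressionResult:
    """OLS of log10 observation frequency in B on that in A, over the
    gene symbols counted in both (each n >= 1)."""
    shared = sorted(
        g for g in set(counts_a) & set(counts_b)
        if counts_a[g] >= 1 and counts_b[g] >= 1
    )
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared gene symbols; need >= 3")
    x = np.log10([counts_a[g] for g in shared])
    y = np.log10([counts_b[g] for g in shared])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r2=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        p_value=float(model.f_pvalue),
        residual_se=float(np.sqrt(model.mse_resid)),
        n=len(shared),
    )


def type2_error(n_restricted: int, n_wide: int) -> float:
    """False-negative rate implied by the restricted analysis:
    1 - n_restricted / n_wide."""
    if n_wide <= 0:
        raise ValueError("n_wide must be positive")
    if n_restricted < 0 or n_restricted > n_wide:
        raise ValueError("need 0 <= n_restricted <= n_wide")
    return 1.0 - n_restricted / n_wide


# ---------------------------------------------------------------------------
# End-to-end pipeline

def predicted_delta_envelope(ground_truth_entries, h_loss_probs):
    """Predicted delta envelope for a simulated run: the mixture of the
    sampled peptides' isotope envelopes convolved with the configured
    hydrogen-rearrangement distribution."""
    seqs = [e.sequence for e in ground_truth_entries]
    uniq, counts = np.unique(seqs, return_counts=True)
    mix: dict[int, float] = {}
    total = counts.sum()
    for seq, cnt in zip(uniq, counts):
        env = isotope_envelope(peptide_composition(seq))
        for k, p in env.offsets.items():
            mix[k] = mix.get(k, 0.0) + p * cnt / total
    norm = sum(mix.values())
    from .insilico import IsotopeEnvelope

    return delta_envelope(
        IsotopeEnvelope({k: p / norm for k, p in mix.items()}), h_loss_probs
    )


@dataclass
class PipelineReport:
    """Everything one pipeline invocation computed."""

    library_size: int
    psms: dict = field(default_factory=dict)       # condition -> list[PSM]
    proteins: dict = field(default_factory=dict)   # condition -> list[ProteinResult]
    profiles: dict = field(default_factory=dict)   # condition -> DeltaMassProfile
    comparisons: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def accepted(self, condition: str) -> set:
        return accepted_gene_symbols(self.proteins[condition])


def run_pipeline(
    sim_config: SimConfig,
    search_config: SearchConfig = SearchConfig(),
    call_config: ProteinCallConfig = ProteinCallConfig(),
    instruments=("OIT_LIKE", "LIT_LIKE"),
    n_random: int | None = None,
    mono_tol: float = 0.1,
    outdir=None,
) -> PipelineReport:
    """Simulate, search (wide window plus its monoisotopic restriction),
    profile delta masses, and call proteins per instrument.

    Conditions are labelled ``{oit|lit}_{wide|mono}``. When ``outdir``
    is given, PSM and protein tables are written there as TSV.
    """
    library = make_library(sim_config)
    index = build_index(library, search_config)
    report = PipelineReport(library_size=len(index))

    for instrument in instruments:
        cfg = replace(sim_config, instrument=instrument)
        spectra, truth = simulate_run(library, cfg)
        blanks = simulate_blank(cfg)
        n_rand = n_random if n_random is not None else cfg.n_spectra
        randoms = generate_random_msms(n_rand, spectra, seed=cfg.seed)

        sample_psms = search_run(spectra, index, search_config)
        blank_psms = search_run(blanks, index, search_config)
        random_psms = search_run(randoms, index, search_config)

        tag = "oit" if instrument == "OIT_LIKE" else "lit"
        sets = {
            f"{tag}_wide": (sample_psms, blank_psms, random_psms),
            f"{tag}_mono": (
                filter_monoisotopic(sample_psms, mono_tol),
                filter_monoisotopic(blank_psms, mono_tol),
                filter_monoisotopic(random_psms, mono_tol),
            ),
        }
        report.ground_truth[tag] = truth
        for cond, (s_psms, b_psms, r_psms) in sets.items():
            report.psms[cond] = s_psms
            report.proteins[cond] = call_proteins(
                s_psms, b_psms, r_psms,
                n_sample_spectra=len(spectra),
                n_random_spectra=len(randoms),
                config=call_config,
            )
            if s_psms:
                bw = 0.01 if instrument == "OIT_LIKE" else 0.1
                profile = detect_integer_peaks(delta_histogram(s_psms, bw))
                predicted = predicted_delta_envelope(
                    truth.entries, sim_config.h_loss_probs
                )
                envelope_agreement(profile, predicted)
                report.profiles[cond] = profile

    # cross-mode and cross-instrument comparisons
    for tag in [t for t in ("oit", "lit") if f"{t}_wide" in report.proteins]:
        wide = report.accepted(f"{tag}_wide")
        mono = report.accepted(f"{tag}_mono")
        report.comparisons[f"{tag}_mono_vs_wide"] = {
            "venn": venn(mono, wide),
            "type2_error": type2_error(len(mono), len(wide)) if wide else None,
            "nested": mono <= wide,
        }
    if "oit_wide" in report.proteins and "lit_wide" in report.proteins:
        counts_a = {r.gene_symbol: r.n for r in report.proteins["oit_wide"] if r.accepted}
        counts_b = {r.gene_symbol: r.n for r in report.proteins["lit_wide"] if r.accepted}
        comp = {"venn": venn(set(counts_a), set(counts_b))}
        try:
            comp["regression"] = log_count_regression(counts_a, counts_b)
        except ValueError:
            comp["regression"] = None
        report.comparisons["oit_vs_lit_wide"] = comp

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, psms in report.psms.items():
            write_results_table(psms, outdir / f"psms_{cond}.tsv", fields=PSM_FIELDS)
        for cond, prots in report.proteins.items():
            write_results_table(
                prots, outdir / f"proteins_{cond}.tsv", fields=PROTEIN_FIELDS
            )
        summary_rows = []
        for cond in report.proteins:
            summary_rows.append(
                {
                    "condition": cond,
                    "accepted_proteins": len(report.accepted(cond)),
                    "accepted_psms": len(report.psms[cond]),
                }
            )
        pd.DataFrame(summary_rows).to_csv(
            outdir / "summary.tsv", sep="\t", index=False
        )
    return report
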