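"""Protein-level statistics from accepted PSMs.

Observation frequencies (spectral counts) of peptide species are
tabulated per gene symbol and corrected against two controls: blank
(noise-only) injections, an analytical control, and random MS/MS
spectra, a statistical control whose counts are rescaled to the sample's
spectrum count. A one-sided chi-square test (chi2 >= 9) removes rows
whose sample counts are explained by the controls. Gene-symbol
cumulative p-values combine the accepted peptide PSM p-values by
Fisher's method; Benjamini-Hochberg step-up converts them to FDR
q-values. A protein is accepted when its chi-square passes, its
spectral count n >= 3, and q <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ProteinCallConfig:
    min_observations: int = 3
    max_q: float = 0.01
    chi2_threshold: float = 9.0
    pseudo_expectation: float = 1.0
    #: additionally drop individual (gene, peptide) rows failing the
    #: chi-square gate before aggregating; the gene-level gate always applies
    row_chi2_filter: bool = False


@dataclass(frozen=True)
class ProteinResult:
    gene_symbol: str
    n: int                   # accepted peptide observations (spectral count)
    distinct_peptides: int
    chi2: float
    chi2_pass: bool
    p_value: float
    q_value: float
    accepted: bool


PROTEIN_FIELDS = [
    "gene_symbol", "n", "distinct_peptides", "chi2", "chi2_pass",
    "p_value", "q_value", "accepted",
]


def tabulate_observations(
    sample_psms,
    blank_psms=(),
    random_psms=(),
    n_sample_spectra: int | None = None,
    n_random_spectra: int | None = None,
) -> pd.DataFrame:
    """Spectral counts per (gene symbol, peptide species) per source.

    Random-control counts are rescaled by (sample spectra / random
    spectra) so they are comparable expectations; without the two totals
    the raw random counts are used unscaled.
    """
    rows: dict[tuple, dict] = {}

    def add(psms, col):
        for p in psms:
            key = (p.gene_symbol, p.peptide_key)
            row = rows.setdefault(
                key, {"n_sample": 0, "n_blank": 0, "n_random": 0}
            )
            row[col] += 1

    add(sample_psms, "n_sample")
    add(blank_psms, "n_blank")
    add(random_psms, "n_random")

    scale = 1.0
    if n_sample_spectra and n_random_spectra:
        scale = n_sample_spectra / n_random_spectra
    records = [
        {
            "gene_symbol": g,
            "peptide_key": k,
            **row,
            "n_random_rescaled": row["n_random"] * scale,
        }
        for (g, k), row in sorted(rows.items())
    ]
    return pd.DataFrame(
        records,
        columns=["gene_symbol", "peptide_key", "n_sample", "n_blank",
                 "n_random", "n_random_rescaled"],
    )


def chi_square_filter(
    n_sample: float,
    n_blank: float = 0.0,
    n_random_rescaled: float = 0.0,
    threshold: float = 9.0,
    pseudo_expectation: float = 1.0,
) -> tuple[float, bool]:
    """One-sided chi-square of sample counts against control expectation.

    E = max(blank + rescaled random, pseudo-expectation); chi2 =
    (n - E)^2 / E when n exceeds E, else 0 (the gate only removes
    observations explained by the controls). Pass requires chi2 >= 9.
    """
    expectation = max(n_blank + n_random_rescaled, pseudo_expectation)
    if n_sample > expectation:
        chi2 = (n_sample - expectation) ** 2 / expectation
    else:
        chi2 = 0.0
    return float(chi2), bool(chi2 >= threshold)


def protein_p_value(peptide_p_values) -> float:
    """Fisher's cumulative p-value over a gene symbol's accepted PSMs.

    X = -2 sum(ln p_i) is chi-square with 2k degrees of freedom under
    the null; the protein p-value is its upper tail probability.
    """
    p = np.asarray(list(peptide_p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no peptide p-values")
    if np.any(p <= 0):
        raise ValueError("p-values must be positive")
    p = np.minimum(p, 1.0)
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, df=2 * p.size))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_proteins(
    sample_psms,
    blank_psms=(),
    random_psms=(),
    n_sample_spectra: int | None = None,
    n_random_spectra: int | None = None,
    config: ProteinCallConfig = ProteinCallConfig(),
) -> list[ProteinResult]:
    """Full protein-level pipeline from BFPS-accepted PSMs.

    Gene-symbol counts aggregated over (gene, peptide species) rows are
    chi-square-tested against the summed control expectation; the gate
    must pass for acceptance alongside n >= 3 and q <= 0.01. With
    ``row_chi2_filter`` each row must additionally pass on its own
    before contributing counts and PSM p-values.
    """
    table = tabulate_observations(
        sample_psms, blank_psms, random_psms, n_sample_spectra, n_random_spectra
    )
    if table.empty:
        return []

    row_pass = {}
    for row in table.itertuples():
        if config.row_chi2_filter:
            _, passed = chi_square_filter(
                row.n_sample, row.n_blank, row.n_random_rescaled,
                config.chi2_threshold, config.pseudo_expectation,
            )
        else:
            passed = True
        row_pass[(row.gene_symbol, row.peptide_key)] = passed

    pvals_by_row: dict[tuple, list] = {}
    for p in sample_psms:
        pvals_by_row.setdefault((p.gene_symbol, p.peptide_key), []).append(p.p_value)

    results = []
    for gene, sub in table.groupby("gene_symbol", sort=True):
        surviving = sub[
            [row_pass[(gene, k)] for k in sub["peptide_key"]]
        ]
        n = int(surviving["n_sample"].sum())
        distinct = int((surviving["n_sample"] > 0).sum())
        gene_chi2, gene_pass = chi_square_filter(
            float(sub["n_sample"].sum()),
            float(sub["n_blank"].sum()),
            float(sub["n_random_rescaled"].sum()),
            config.chi2_threshold,
            config.pseudo_expectation,
        )
        pv = [
            p
            for k in surviving["peptide_key"]
            for p in pvals_by_row.get((gene, k), [])
        ]
        p_gene = protein_p_value(pv) if pv else 1.0
        results.append(
            ProteinResult(
                gene_symbol=gene, n=n, distinct_peptides=distinct,
                chi2=gene_chi2, chi2_pass=gene_pass, p_value=p_gene,
                q_value=1.0, accepted=False,
            )
        )

    q = bh_fdr([r.p_value for r in results])
    final = []
    for r, qi in zip(results, q):
        accepted = (
            r.chi2_pass
            and r.n >= config.min_observations
            and qi <= config.max_q
        )
        final.append(
            ProteinResult(
                gene_symbol=r.gene_symbol, n=r.n,
                distinct_peptides=r.distinct_peptides, chi2=r.chi2,
                chi2_pass=r.chi2_pass, p_value=r.p_value,
                q_value=float(qi), accepted=accepted,
            )
        )
    final.sort(key=lambda r: (-r.n, r.gene_symbol))
    return final


def accepted_gene_symbols(results) -> set:
    return {r.gene_symbol for r in results if r.accepted}
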