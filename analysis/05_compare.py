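"""Cross-mode and cross-instrument comparisons of the protein calls.

Computes the Venn overlaps of accepted gene symbols, the type-II error
implied by restricting to the monoisotopic mass, and the regression of
log10 peptide observation frequencies between the two instruments.

Writes results/compare/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from openps.compare import log_count_regression, type2_error, venn
from openps.io_formats import read_results_table

PROTEINS = Path(__file__).resolve().parents[1] / "results" / "proteins"
OUT = Path(__file__).resolve().parents[1] / "results" / "compare"


def accepted(tag):
    df = read_results_table(PROTEINS / f"proteins_{tag}.tsv")
    acc = df[df.accepted]
    return dict(zip(acc.gene_symbol, acc.n))


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    for tag in ("oit", "lit"):
        mono = accepted(f"{tag}_mono")
        wide = accepted(f"{tag}_wide")
        nested = set(mono) <= set(wide)
        err = type2_error(len(mono), len(wide)) if wide else None
        report[f"{tag}_mono_vs_wide"] = {
            "venn": venn(mono, wide),
            "nested": nested,
            "type2_error": err,
        }
        print(f"{tag}: mono {len(mono)} in wide {len(wide)} "
              f"(nested={nested}); restricting to the monoisotopic mass "
              f"forfeits {err:.0%} of accepted proteins" if err is not None
              else f"{tag}: no accepted proteins")

    oit, lit = accepted("oit_wide"), accepted("lit_wide")
    report["oit_vs_lit"] = {"venn": venn(oit, lit)}
    try:
        reg = log_count_regression(oit, lit)
        report["oit_vs_lit"]["regression"] = asdict(reg)
        print(f"OIT vs LIT log10-count regression over {reg.n} shared gene "
              f"symbols: slope {reg.slope:.3f}, adjusted R^2 {reg.adj_r2:.3f}, "
              f"F = {reg.f_statistic:.1f} on (1, {reg.df_resid}) df, "
              f"p = {reg.p_value:.2e}")
    except ValueError as exc:
        report["oit_vs_lit"]["regression"] = None
        print(f"regression skipped: {exc}")

    (OUT / "comparisons.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT / 'comparisons.json'}")


if __name__ == "__main__":
    main()
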