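"""Protein-level calls from the PSM tables.

For each instrument and window condition: tabulate spectral counts per
gene symbol, correct against the blank and (rescaled) random controls
with the chi-square >= 9 gate, combine PSM p-values into gene-symbol
cumulative p-values, convert to Benjamini-Hochberg q-values, and accept
proteins with n >= 3 and q <= 0.01.

Writes results/proteins/.
"""

from pathlib import Path

import pandas as pd

from openps.io_formats import read_manifest, read_results_table, write_results_table
from openps.protein_stats import PROTEIN_FIELDS, call_proteins
from openps.search import PSM

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
SEARCH = Path(__file__).resolve().parents[1] / "results" / "search"
OUT = Path(__file__).resolve().parents[1] / "results" / "proteins"


def load_psms(path):
    df = read_results_table(path)
    return [PSM(**{k: row[k] for k in df.columns}) for _, row in df.iterrows()]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    manifests = read_manifest(SIM / "manifest.tsv")
    by_kind = {}
    for m in manifests:
        by_kind.setdefault((m.instrument_label, m.run_kind), []).append(m)

    for instrument in ("OIT_LIKE", "LIT_LIKE"):
        sample = by_kind[(instrument, "SAMPLE")][0]
        random_m = by_kind[(instrument, "RANDOM")][0]
        blank_m = by_kind.get(("OIT_LIKE", "BLANK"), [None])[0]
        for mode, suffix in (("wide", ""), ("mono", "_mono")):
            sample_psms = load_psms(SEARCH / f"psms_{sample.run_id}{suffix}.tsv")
            random_psms = load_psms(SEARCH / f"psms_{random_m.run_id}{suffix}.tsv")
            blank_psms = load_psms(SEARCH / f"psms_{blank_m.run_id}{suffix}.tsv")
            results = call_proteins(
                sample_psms, blank_psms, random_psms,
                n_sample_spectra=sample.spectrum_count,
                n_random_spectra=random_m.spectrum_count,
            )
            tag = f"{'oit' if instrument == 'OIT_LIKE' else 'lit'}_{mode}"
            write_results_table(results, OUT / f"proteins_{tag}.tsv",
                                fields=PROTEIN_FIELDS)
            n_acc = sum(r.accepted for r in results)
            print(f"{tag}: {n_acc} gene symbols accepted "
                  f"(n >= 3, chi2 >= 9, q <= 0.01) of {len(results)} observed")


if __name__ == "__main__":
    main()
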