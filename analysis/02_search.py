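"""Open-window search of the simulated runs.

Reads results/sim/ (manifest + FASTA + MGF), searches every run under
the wide -3/+5 Da precursor window with the E3 intensity filter and
best-fit-per-spectrum selection at p <= 0.01, and writes one PSM table
per run plus the monoisotopic (|delta m| <= 0.1 Da) restriction of each.

Writes results/search/.
"""

from pathlib import Path

from openps.io_formats import read_fasta, read_manifest, read_mgf, write_results_table
from openps.search import (
    PSM_FIELDS,
    SearchConfig,
    build_index,
    filter_monoisotopic,
    search_run,
)

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results" / "search"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    library = read_fasta(SIM / "library.fasta")
    config = SearchConfig()
    index = build_index(library, config)
    print(f"peptide index: {len(index)} species from {len(library)} proteins")

    for manifest in read_manifest(SIM / "manifest.tsv"):
        spectra = read_mgf(SIM / manifest.file_path, default_run_id=manifest.run_id)
        psms = search_run(spectra, index, config)
        write_results_table(psms, OUT / f"psms_{manifest.run_id}.tsv",
                            fields=PSM_FIELDS)
        mono = filter_monoisotopic(psms)
        write_results_table(mono, OUT / f"psms_{manifest.run_id}_mono.tsv",
                            fields=PSM_FIELDS)
        print(f"{manifest.run_id} ({manifest.run_kind}): "
              f"{len(psms)}/{len(spectra)} spectra accepted at p <= "
              f"{config.max_psm_p} ({len(mono)} monoisotopic)")


if __name__ == "__main__":
    main()
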