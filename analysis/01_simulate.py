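"""Simulate the study's inputs: a protein library (FASTA), OIT-like and
LIT-like sample runs, a blank (noise-only) run, and a random-spectrum
statistical control, all as MGF plus a run manifest and ground truth.

Writes results/sim/.
"""

from dataclasses import asdict, replace
from pathlib import Path

import pandas as pd

from openps.io_formats import RunManifest, write_fasta, write_manifest, write_mgf
from openps.synthetic_data import (
    SimConfig,
    generate_random_msms,
    make_library,
    simulate_blank,
    simulate_run,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(seed=SEED, n_spectra=600, n_blank_spectra=150)
    library = make_library(sim)
    write_fasta(library, OUT / "library.fasta")
    print(f"library: {len(library)} proteins "
          f"({sim.n_absent_proteins} held out of the sample)")

    manifests = []
    truths = []
    for instrument in ("OIT_LIKE", "LIT_LIKE"):
        cfg = replace(sim, instrument=instrument)
        spectra, truth = simulate_run(library, cfg)
        run_file = OUT / f"{truth.run_id}.mgf"
        write_mgf(spectra, run_file)
        manifests.append(RunManifest(truth.run_id, instrument, "SAMPLE",
                                     len(spectra), run_file.name))
        truths.extend(asdict(e) for e in truth.entries)

        randoms = generate_random_msms(cfg.n_spectra, spectra, seed=cfg.seed,
                                       run_id=f"random_{truth.run_id}")
        rand_file = OUT / f"random_{truth.run_id}.mgf"
        write_mgf(randoms, rand_file)
        manifests.append(RunManifest(f"random_{truth.run_id}", instrument,
                                     "RANDOM", len(randoms), rand_file.name))
        print(f"{instrument}: {len(spectra)} sample + {len(randoms)} random spectra")

    blanks = simulate_blank(sim)
    blank_file = OUT / f"blank_s{SEED}.mgf"
    write_mgf(blanks, blank_file)
    manifests.append(RunManifest(f"blank_s{SEED}", "OIT_LIKE", "BLANK",
                                 len(blanks), blank_file.name))
    print(f"blank: {len(blanks)} noise-only spectra")

    write_manifest(manifests, OUT / "manifest.tsv")
    pd.DataFrame(truths).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)
    print(f"wrote manifest and ground truth under {OUT}")


if __name__ == "__main__":
    main()
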