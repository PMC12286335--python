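"""Simulate imputed genotype dosages over the 140-variant risk panel.

Draws per-variant risk-allele frequencies from Uniform(0.05, 0.5), then
samples one dosage in [0, 2] per participant and variant (hard calls
perturbed by imputation-like noise), and writes the dosage matrix plus a
PLINK-score-style risk-variant file for the scoring step.
"""

import numpy as np

from common import DOSAGE_FILE, N_PARTICIPANTS, N_VARIANTS, SCRATCH, SEED, VARIANT_FILE
from geoscreen import SyntheticGenotypeSpec, simulate_genotypes
from geoscreen.io import write_dosage_tsv


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    freqs = rng.uniform(0.05, 0.5, N_VARIANTS)
    spec = SyntheticGenotypeSpec(
        n_variants=N_VARIANTS, allele_freqs=freqs, dosage_mode="dosage",
        seed=SEED + 1,
    )
    dosages = simulate_genotypes(spec, N_PARTICIPANTS)
    write_dosage_tsv(dosages, DOSAGE_FILE)

    with open(VARIANT_FILE, "w") as fh:
        for j, vid in enumerate(dosages.columns):
            allele = rng.choice(list("ACGT"))
            fh.write(f"{vid} {allele} {rng.normal(0.1, 0.03):.4f}\n")

    print(f"simulated {dosages.shape[0]} samples x {dosages.shape[1]} variants")
    print(f"mean dosage {dosages.to_numpy().mean():.3f} "
          f"(expected ~{2 * freqs.mean():.3f} from the drawn frequencies)")
    print(f"wrote {DOSAGE_FILE} and {VARIANT_FILE}")


if __name__ == "__main__":
    main()
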