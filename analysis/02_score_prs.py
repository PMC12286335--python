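"""Compute polygenic risk scores and the high/low dichotomy.

Scores each participant as the unweighted sum of risk-allele dosages
over the 140-variant panel and labels the top 5% of scores as the
high-PRS group, the categorization the downstream regression uses.
"""

from common import DOSAGE_FILE, HIGH_PRS_FRACTION, PRS_FILE, VARIANT_FILE
from geoscreen import prs_results, read_dosage_tsv, read_variant_table


def main() -> None:
    dosages = read_dosage_tsv(DOSAGE_FILE)
    variants = read_variant_table(VARIANT_FILE)
    out = prs_results(dosages, variants, weighted=False,
                      high_fraction=HIGH_PRS_FRACTION)
    out.to_csv(PRS_FILE, index=False)

    n_high = (out["category"] == "high").sum()
    print(f"scored {len(out)} participants over {len(variants.variant_ids)} variants")
    print(f"PRS median {out['score'].median():.1f}, "
          f"range {out['score'].min():.1f}-{out['score'].max():.1f}")
    print(f"high-PRS group: {n_high} ({100 * n_high / len(out):.1f}%)")
    print(f"wrote {PRS_FILE}")


if __name__ == "__main__":
    main()
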