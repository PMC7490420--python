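"""Exposure-outcome harmonization on deliberately corrupted records.

The outcome file reports some variants on the opposite strand, some with
the allele coding swapped, and some as palindromic A/T / C/G variants;
harmonization must align every effect onto the exposure's effect allele
before any estimator can run.
"""

from predimr import MrSimConfig, gen_mr_dataset, harmonize

cfg = MrSimConfig(
    n_snps=24,
    frac_strand_flip=0.25,   # reported on the other strand (content unchanged)
    frac_allele_swap=0.25,   # effect/other alleles swapped (sign must flip)
    frac_palindromic=0.25,   # A/T, C/G: resolved by allele frequency
    seed=3,
)
exposure, outcome, _, _, truth = gen_mr_dataset(cfg)

instruments = harmonize(exposure, outcome, palindrome_policy="infer")

print("harmonization actions:")
for action, count in instruments.log["action"].value_counts().items():
    print(f"  {action:20s} {count}")

t = truth.per_snp.set_index("rsid")
got = instruments.df.set_index("rsid")
err_g = (got["gamma"] - t.loc[got.index, "gamma_oriented"]).abs().max()
err_G = (got["Gamma"] - t.loc[got.index, "Gamma_oriented"]).abs().max()
print(f"\nrecovered {instruments.n_snps}/{cfg.n_snps} effect pairs; "
      f"max |error| vs pre-corruption truth: gamma {err_g:.1e}, Gamma {err_G:.1e}")
print("(zero error: every corruption was undone exactly)")
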