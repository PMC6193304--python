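"""Null expectation of apparent abundance changes after loss of dominants.

Runs a small ensemble of the sampling-theory null model: each iteration
draws a lognormal community with a logistic abundance-viability curve,
sequences it at fixed depth, removes the 10-65 most abundant taxa and
sequences again.  Prints the mean apparent log10-fold change for rare and
low-density taxa.
"""

import numpy as np

import dustlight as dl

summary = dl.run_ensemble(200, dl.ParamRanges(), seed=0, keep_records=True)
records = summary.records

ab = records["abundance"].to_numpy()
ch = records["change"].to_numpy()
low_decile = ab <= np.quantile(ab, 0.10)
below_500 = ab < 500.0

print(f"iterations: {summary.n_iterations}, taxon records: {summary.n_records}")
print(f"mean apparent change, lowest abundance decile: {ch[low_decile].mean():+.4f}")
print(f"fraction of taxa <500 copies/mg with |change| < 0.5: "
      f"{np.mean(np.abs(ch[below_500]) < 0.5):.3f}")
print()
print("A positive mean for the rarest taxa means they *appear* to increase")
print("after dominant taxa are lost, purely because sequencing re-allocates")
print("reads; most low-density taxa nonetheless show only small changes.")
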