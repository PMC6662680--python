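"""Quality control on a dataset with planted genotyping problems.

Starts from a clean simulated dataset and plants one problem per SNP:
8% random allele-call errors at SNP 0 (Mendelian inconsistencies and a
Hardy-Weinberg departure), a duplicated column at SNP 2 (perfect LD
with SNP 1), and 8% missing calls at SNP 3. The report shows each
filter catching its target while the clean SNPs pass.
"""

import numpy as np

from pooxe import MISSING, SimParams, inject_errors, run_qc, simulate_dataset

clean = simulate_dataset(
    SimParams(n_unexposed_families=1000, n_exposed_families=0, n_effect_snps=6, seed=11)
)
noisy = inject_errors(clean, rate=0.08, seed=12)
# keep the injected errors at SNP 0 only; restore the rest
for noisy_arr, clean_arr in ((noisy.mother, clean.mother), (noisy.father, clean.father),
                             (noisy.child, clean.child)):
    noisy_arr[:, 1:] = clean_arr[:, 1:]
    noisy_arr[:, 2] = clean_arr[:, 1]  # SNP 2 := copy of SNP 1 (r^2 = 1)
rng = np.random.default_rng(13)
drop = rng.random(1000) < 0.08
for arr in (noisy.mother, noisy.father, noisy.child):
    arr[drop, 3] = MISSING

report, filtered = run_qc(noisy)
print(report.to_frame().to_string(index=False))
print()
print(report.metrics_frame().to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\nretained {filtered.n_snps} of {report.total_snps} SNPs")

# Each criterion row counts failures independently (a SNP can fail
# several), while the remaining-SNPs row reflects unique removals;
# perfect-LD pruning keeps the first SNP of the correlated pair.
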