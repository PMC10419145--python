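"""Recovering hydrolysis rate constants from noisy bond kinetics.

Generates a synthetic hydrolyzed-fraction time course for every active bond
(Gaussian noise, fixed seed), fits the demask-then-cleave form with kdf
fixed at 0.46 min^-1, and prints the estimates next to the generating
values, plus rates relative to the reference bond 8.
"""

from pepdemask import SyntheticSpec, fit_kj, generate_bond_dataset, relative_rates

dataset = generate_bond_dataset(SyntheticSpec(seed=42, noise_sd=0.02))

generating = {"8": 0.46, "14": 0.53, "40": 1.41, "141": 1.058, "148": 1.61}
estimates = {}
print("bond    k_true    k_hat   stderr")
for label, k_true in generating.items():
    est = fit_kj(dataset[label])
    estimates[label] = est
    print(f"{label:6s}  {k_true:6.3f}  {est.k_hat:6.3f}   {est.stderr:6.3f}")

rel = relative_rates(estimates, "8")
print("\nrelative to bond 8:", {k: round(v, 2) for k, v in rel.items()})
print("With six time points and 2 % noise the estimates carry ~5-10 %")
print("uncertainty; the reported stderr quantifies it per bond.")
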