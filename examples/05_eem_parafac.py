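"""PARAFAC decomposition of excitation-emission fluorescence landscapes.

Simulates 4-component EEMs (two protein-like, two humic-like fluorophores)
at SNR 20 and recovers the components by nonnegative alternating least
squares, scoring recovery by Tucker congruence against the ground truth.
"""
from domfinger import ExperimentDesign, simulate_eems
from domfinger.parafac import component_peaks, congruence, fit_parafac

design = ExperimentDesign()
eems = simulate_eems(design, snr=20.0, seed=1)
print(f"EEM stack: {eems.data.shape[0]} samples, "
      f"{len(eems.excitation_nm)} excitation x {len(eems.emission_nm)} emission points")

model = fit_parafac(eems, n_components=4, n_restarts=2, max_iter=600,
                    tol=1e-11, seed=1)
print(f"fit: {model.fit:.5f} explained sum of squares, "
      f"{model.n_iter} iterations, converged={model.converged}")

cong, perm = congruence(model, eems.true_ex_loadings, eems.true_em_loadings)
for k, peak in enumerate(component_peaks(model)):
    true_ex, true_em = eems.component_peaks[perm[k]]
    print(f"component {k + 1}: Ex/Em {peak.excitation_nm:g}/{peak.emission_nm:g} nm "
          f"(truth {true_ex:g}/{true_em:g}), congruence {cong[k]:.4f}")
# congruence ~1 and peaks within a grid step: the trilinear structure is
# fully identifiable at this noise level.
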