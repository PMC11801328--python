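"""Simulate one voxel and recover its parameters with both models.

The voxel follows the two-compartment T2*-IVIM model; fitting it with
the mono-exponential T2*-ADC model yields an effective T2* between the
two compartments, while the IVIM fit recovers all six parameters.  With
Rician noise at SNR 30 the fits use the exact Rician expectation of the
magnitude so the noise floor does not bias the estimates.
"""

from placenta_dwr import (
    FitConfig,
    IvimParams,
    add_noise,
    build_protocol_scheme,
    fit_ivim,
    fit_monoexp,
    signal_ivim,
)

scheme = build_protocol_scheme()
truth = IvimParams(s0=100, f=0.3, t2_star_fast=80, t2_star_slow=40,
                   d_star=0.05, adc=2e-3)
clean = signal_ivim(truth, scheme)

print("noiseless fits")
mono = fit_monoexp(clean, scheme)
print(f"  T2*-ADC : T2* = {mono.params.t2_star:6.2f} ms (effective, between "
      f"{truth.t2_star_slow:g} and {truth.t2_star_fast:g}), "
      f"ADC = {mono.params.adc:.2e} mm^2/s")
ivim = fit_ivim(clean, scheme, "full")
p = ivim.params
print(f"  T2*-IVIM: f = {p.f:.3f}, T2*f = {p.t2_star_fast:.1f} ms, "
      f"T2*s = {p.t2_star_slow:.1f} ms, D* = {p.d_star:.3f}, ADC = {p.adc:.2e}")

sigma = truth.s0 / 30  # SNR 30
noisy = add_noise(clean, sigma, "rician", seed=1)
corrected = fit_ivim(noisy, scheme, "full", FitConfig(sigma=sigma))
p = corrected.params
print(f"\nRician noise, SNR 30 (expectation-corrected full fit)")
print(f"  f = {p.f:.3f}, T2*f = {p.t2_star_fast:.1f} ms, "
      f"T2*s = {p.t2_star_slow:.1f} ms, ADC = {p.adc:.2e}")
print("  (truth: f = 0.300, T2*f = 80.0 ms, T2*s = 40.0 ms, ADC = 2.00e-03;")
print("   the fast compartment scatters most at single-voxel level, which is")
print("   why the analysis averages over the whole parenchyma ROI)")
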