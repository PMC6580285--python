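"""Compare four Gulf Coast avian hybrid zones: width vs dispersal vs divergence.

Uses the packaged literature-transcribed records (red-shouldered hawk,
barred owl, red-bellied woodpecker, Carolina chickadee) to ask whether
zone width tracks gene flow (dispersal sigma) or genetic divergence.
"""

from hybridcline import rms_dispersal, sigma_from_mean_se, zone_comparison
from hybridcline.dispersal import POECILE_CAROLINENSIS_DISTANCES

comp = zone_comparison()
print(comp["table"].to_string(index=False))

print(f"\nwidth max/min ratio        = {comp['width_ratio']:.1f}")
print(f"r(width, dispersal sigma)  = {comp['r_width_sigma']:.2f}")
print(f"r(width, ND2 divergence)   = {comp['r_width_divergence']:.2f}")
print("\nWidth scales strongly with dispersal (r near +1) but only weakly")
print("and negatively with divergence: the zones look dispersal-limited,")
print("as neutral secondary-contact diffusion predicts (width ~ sigma*sqrt(t)).")

print("\ngene-flow estimators:")
print(f"  RMS of chickadee anecdotal distances {POECILE_CAROLINENSIS_DISTANCES}: "
      f"{rms_dispersal(POECILE_CAROLINENSIS_DISTANCES):.2f} km")
print(f"  sqrt(N)*SE with SE=11.24 km, N=100:  "
      f"{sigma_from_mean_se(11.24, 100):.1f} km "
      "(recovers the sample SD of dispersal distances)")
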