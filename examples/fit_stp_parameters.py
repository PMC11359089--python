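"""Recover free short-term-plasticity parameters from stimulus targets.

Targets are the per-burst mean amplitudes of a 10-burst theta-burst
protocol (bursts 1, 2, 8, 10) plus paired-pulse ratios at 25, 50, 100
and 200 ms.  Here the targets are generated from known parameters, so
the fit can be checked against the truth — the validation strategy when
no experimental recordings are bundled.
"""

import synaptome_sd as sd
from synaptome_sd.fitting import DEFAULT_FREE, make_targets

truth = sd.STPParams(a_d0=0.12, tau_d0=250.0, a_f0=0.30)
targets = make_targets(truth)
print("theta-burst targets:", {k: round(v, 4) for k, v in
                               targets.burst_targets.items()})
print("paired-pulse targets:", {k: round(v, 4) for k, v in
                                targets.ppf_targets.items()})

result = sd.fit_stp(targets, free=DEFAULT_FREE)
print(f"\nresidual sum of squares: {result.residual:.2e}")
for name in DEFAULT_FREE:
    print(f"  {name}: fitted {getattr(result.params, name):.4f} "
          f"(truth {getattr(truth, name):.4f})")
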