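"""Cycle length of a 10 Hz probe trace by the autocorrelation rule.

A 15-minute flow-style trace with a 0.1 Hz oscillation is band-limited to
0.0095-0.20 Hz; the first local minimum (tau1, half cycle) and the first
local maximum after it (tau2, full cycle) of the autocorrelation give the
cycle length when A(tau1) < 0 < A(tau2).
"""

from facewave import CYCLE_BAND, SceneConfig, cycle_length, generate_probe_trace

cfg = SceneConfig(grid_shape=(4, 4), duration=900.0, seed=0)
trace = generate_probe_trace(cfg, kind="flow")
res = cycle_length(trace, band=CYCLE_BAND)

print(f"trace: {trace.duration:.0f} s at {trace.sample_rate} Hz")
print(f"tau1 (half cycle):  {res.tau1:.2f} s, A(tau1) = "
      f"{res.A[int(res.tau1 * trace.sample_rate)]:+.3f}")
print(f"tau2 (full cycle):  {res.tau2:.2f} s, A(tau2) = "
      f"{res.A[int(res.tau2 * trace.sample_rate)]:+.3f}")
print(f"cycle length:       {res.cycle_length:.2f} s ({res.verdict_reason}); "
      f"the configured wave period is {1 / cfg.f_slow:.0f} s")

# on a structureless trace the rule reports whatever qualifying pair the
# band-limited noise happens to contain — or indeterminate if there is none;
# no frequency claim is attached to such a verdict
flat = SceneConfig(grid_shape=(4, 4), duration=900.0, amp_slow=1e-9,
                   amp_heart=0.0, noise_sd=1.0, seed=1)
res_flat = cycle_length(generate_probe_trace(flat), band=CYCLE_BAND)
print(f"pure-noise trace verdict: {res_flat.verdict_reason}"
      + (f" (tau2 = {res_flat.cycle_length:.1f} s, meaningless without "
         "oscillatory structure)" if res_flat.determinate else ""))
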