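"""Derive the reported sleep measures from one hypnogram.

TIB, TST, SOL, WASO, sleep efficiency and REM latency are all functions
of the per-second stage stream; SOL + TST + WASO = TIB holds exactly.
"""

from cstval import derive_measures
from cstval.simulate import SleepArchitectureParams, simulate_psg

night = simulate_psg(SleepArchitectureParams(), seed=42)
m = derive_measures(night)

print(f"time in bed        : {m.tib_h:6.2f} h")
print(f"sleep onset latency: {m.sol_h:6.2f} h")
print(f"total sleep time   : {m.tst_h:6.2f} h")
print(f"wake after onset   : {m.waso_h:6.2f} h")
print(f"sleep efficiency   : {m.se_pct:6.2f} %")
print(f"REM latency        : {m.rem_latency_min:6.1f} min after sleep onset")
print(f"partition check    : SOL+TST+WASO-TIB = "
      f"{m.sol_h + m.tst_h + m.waso_h - m.tib_h:+.1e} h")
# Sleep efficiency is the share of the night actually spent asleep; the
# partition check shows the three components tile the night exactly.
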