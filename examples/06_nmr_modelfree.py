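"""Model-free analysis of backbone 15N relaxation data.

Forward-models R1/R2/NOE for a 40-residue synthetic protein tumbling at
tau_m = 14.7 ns (800 MHz), with a flexible tail and one
exchange-broadened residue, then runs the full analysis: tau_m
estimation, per-residue Lipari-Szabo fits, and R2/R1 classification.
"""

import numpy as np

import loopmsm as lm

n = 40
S2 = np.full(n, 0.87)
S2[30:] = np.linspace(0.8, 0.45, 10)       # increasingly mobile tail
te = np.full(n, 40.0)
te[30:] = 400.0
rex = np.zeros(n)
rex[15] = 6.0                               # one exchange-broadened residue

truth = lm.RelaxationTruth(
    S2_true=S2, tau_e_true=te, tau_m_true=14.7, field_MHz=800.0,
    noise_sd={"R1": 0.01, "R2": 0.3, "NOE": 0.01}, rex_true=rex,
)
ds = lm.gen_relaxation_data(truth, seed=7)

tau_m = lm.estimate_tm(ds)
print(f"estimated tau_m: {tau_m:.1f} ns (true 14.7)")

mf = lm.modelfree_fit(ds, tau_m_ns=tau_m)
print(f"mean |S2 error|: {np.nanmean(np.abs(mf.S2 - S2)):.3f}")
print(f"residue 16 model: {mf.model[15]} (Rex = {mf.rex[15]:.1f} s^-1, true 6.0)")
print(f"tail S2 (residues 31-40): {np.round(mf.S2[30:], 2)}")

cls = lm.classify_r2r1(ds)
print(f"R2/R1 mean {cls.mean:.1f} +- {cls.sd:.1f}")
print("slow (us-ms) residues:",
      [int(r) for r, c in zip(cls.residue, cls.classes) if c == "slow"])
print("fast (ps-ns) residues:",
      [int(r) for r, c in zip(cls.residue, cls.classes) if c == "fast"])
# -> the planted Rex residue lands above mean + 1 SD ("slow"); the mobile
#    tail falls below mean - 1 SD ("fast"); S2 tracks the planted profile.
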