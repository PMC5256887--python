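"""Force-dependent unbinding of actin cross-linkers (Bell slip bond).

Prints the unbinding rate of an ACP arm as a function of the extensional
force it carries.  Stretched arms unbind exponentially faster (slip bond,
parameters mimicking filamin A); compressed arms stay at the zero-force
rate.  This asymmetry, opposed to the motors' catch bond, is what lets
motors stay put under load while cross-linkers keep remodeling.
"""
import numpy as np

from actomyo import ParameterSet, acp_unbind_rate

p = ParameterSet()
print(f"zero-force unbinding rate: {p.k_ub0_acp} 1/s")
print(f"force sensitivity lambda:  {p.lambda_acp} nm\n")
print(" force (pN)   rate stretched (1/s)   rate compressed (1/s)")
for f in np.arange(0.0, 201.0, 25.0):
    k_stretched = acp_unbind_rate(f, p.r0_acp + 1.0, p)
    k_compressed = acp_unbind_rate(f, p.r0_acp - 1.0, p)
    print(f"   {f:6.0f}       {k_stretched:12.3f}           {k_compressed:10.3f}")
print("\nmean attachment lifetime falls from "
      f"{1 / p.k_ub0_acp:.1f} s unloaded to "
      f"{1 / acp_unbind_rate(200.0, p.r0_acp, p):.2f} s at 200 pN")
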