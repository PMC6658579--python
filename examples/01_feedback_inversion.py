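"""Invert an operator by high-gain feedback, without an analytic inverse.

The loop settles where q = g(p - S q); for the scalar map S: q -> 2q the
equilibrium is g*p/(1 + 2g), which approaches the true inverse p/2 = 0.5
as the gain grows.
"""

import numpy as np

from fitloop import GenericOperator, InversionConfig, invert_fixed_point

S = GenericOperator(forward=lambda q: 2.0 * q, m_in=1, m_out=1)
p = np.array([1.0])

print("gain      solution   error vs true inverse (0.5)")
for gain in (10, 100, 1000):
    res = invert_fixed_point(S, p, InversionConfig(gain=gain))
    print(f"{gain:5d}   {res.q[0]:.6f}   {abs(res.q[0] - 0.5):.2e}")

print()
print("Each 10x gain cuts the inversion error ~10x: the feedback loop")
print("acts as S^-1 without ever representing the inverse explicitly.")
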