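"""Exact derivatives from dual-number arithmetic.

A dual number x + y*eps (with eps^2 = 0) pushed through ordinary arithmetic
carries f(x) in its real part and f'(x)*y in its dual part — no symbolic
differentiation, no finite-difference truncation error.
"""

from dualda import DualScalar, MultiDualScalar
from dualda import dual as dm


def f(x):
    return 2.0 * (x - 1.0) ** 2 + 3.0  # f'(x) = 4(x - 1)


d = DualScalar(3.0, 1.0)  # evaluate at x=3, seed the derivative direction
r = f(d)
print(f"f(3)  = {r.real}   (expected 11)")
print(f"f'(3) = {r.dual}   (expected 4*(3-1) = 8)")

# the same works through any composition of overloaded functions
g = dm.exp(dm.sin(DualScalar(0.8, 1.0)) * 0.5)
print(f"d/dx exp(sin(x)/2) at 0.8 = {g.dual:.12f}")

# a multi-dual scalar batches several derivative directions in ONE pass:
# seeding with unit vectors yields all partials of an expression at once
x = MultiDualScalar(1.2, [1.0, 0.0])
y = MultiDualScalar(0.7, [0.0, 1.0])
h = x * y + dm.log(x) / y
print(f"h(x,y) = {h.real:.6f}, dh/dx = {h.duals[0]:.6f}, dh/dy = {h.duals[1]:.6f}")
print("(dh/dx = y + 1/(x y), dh/dy = x - log(x)/y^2)")
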