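"""Dual-number scalars for forward-mode automatic differentiation.

A dual number ``d = x + y*eps`` extends the reals with a nilpotent element
``eps`` satisfying ``eps**2 = 0``.  Evaluating a differentiable function on
``x + y*eps`` yields ``f(x) + f'(x)*y*eps``: the dual part carries the exact
first derivative alongside the value, with no truncation error.  The
multi-dual variant carries ``n`` mutually annihilating dual parts
(``eps_i * eps_j = 0`` for all ``i, j``) and batches ``n`` directional
derivatives into a single evaluation that shares one real part.

Both types overload arithmetic, comparisons and the elementary functions in
this module, so model code written against plain floats runs unchanged on
dual inputs.  Comparisons order by the real part only: control flow in
overloaded code follows the nonlinear trajectory, which is the piecewise
linearization implicit in operator-overloading AD.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

__all__ = [
    "DualScalar",
    "MultiDualScalar",
    "DualDomainError",
    "DualShapeError",
    "exp",
    "log",
    "sqrt",
    "sin",
    "cos",
    "tanh",
    "power",
    "maximum",
    "minimum",
    "real_part",
    "dual_part",
]

_REALS = (int, float, np.integer, np.floating)

Number = Union[int, float, np.integer, np.floating]


class DualDomainError(ValueError):
    """An elementary function was evaluated where its derivative is undefined."""


class DualShapeError(ValueError):
    """Multi-dual operands disagree on the number of dual parts."""


class DualScalar:
    """A number ``real + dual*eps`` with ``eps**2 = 0``.

    Arithmetic propagates exact first derivatives: if the inputs of an
    expression are seeded with ``dual`` equal to a perturbation direction,
    the result's ``dual`` is the directional derivative of the expression.
    """

    __slots__ = ("real", "dual")

    def __init__(self, real: Number, dual: Number = 0.0):
        self.real = float(real)
        self.dual = float(dual)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, DualScalar):
            return DualScalar(self.real + other.real, self.dual + other.dual)
        if isinstance(other, _REALS):
            return DualScalar(self.real + other, self.dual)
        return NotImplemented

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, DualScalar):
            return DualScalar(self.real - other.real, self.dual - other.dual)
        if isinstance(other, _REALS):
            return DualScalar(self.real - other, self.dual)
        return NotImplemented

    def __rsub__(self, other):
        if isinstance(other, _REALS):
            return DualScalar(other - self.real, -self.dual)
        return NotImplemented

    def __mul__(self, other):
        if isinstance(other, DualScalar):
            return DualScalar(
                self.real * other.real,
                self.real * other.dual + self.dual * other.real,
            )
        if isinstance(other, _REALS):
            return DualScalar(self.real * other, self.dual * other)
        return NotImplemented

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, DualScalar):
            if other.real == 0.0:
                raise ZeroDivisionError(
                    "dual division: denominator has zero real part"
                )
            return DualScalar(
                self.real / other.real,
                (self.dual * other.real - self.real * other.dual)
                / (other.real * other.real),
            )
        if isinstance(other, _REALS):
            if other == 0:
                raise ZeroDivisionError("dual division: zero denominator")
            return DualScalar(self.real / other, self.dual / other)
        return NotImplemented

    def __rtruediv__(self, other):
        if isinstance(other, _REALS):
            if self.real == 0.0:
                raise ZeroDivisionError(
                    "dual division: denominator has zero real part"
                )
            return DualScalar(
                other / self.real, -other * self.dual / (self.real * self.real)
            )
        return NotImplemented

    def __pow__(self, p):
        if isinstance(p, _REALS):
            return _dual_power(self, float(p))
        return NotImplemented

    def __rpow__(self, base):
        # b ** d = exp(d * log b) for constant b > 0
        if isinstance(base, _REALS):
            if base <= 0:
                raise DualDomainError(
                    f"power: non-positive base {base} with dual exponent"
                )
            v = base ** self.real
            return DualScalar(v, v * math.log(base) * self.dual)
        return NotImplemented

    def __neg__(self):
        return DualScalar(-self.real, -self.dual)

    def __pos__(self):
        return self

    def __abs__(self):
        # subgradient convention: sign(0) = 0
        s = 1.0 if self.real > 0.0 else (-1.0 if self.real < 0.0 else 0.0)
        return DualScalar(abs(self.real), s * self.dual)

    # -- comparisons: real part only --------------------------------------

    def __lt__(self, other):
        return self.real < _real_of(other)

    def __le__(self, other):
        return self.real <= _real_of(other)

    def __gt__(self, other):
        return self.real > _real_of(other)

    def __ge__(self, other):
        return self.real >= _real_of(other)

    def __eq__(self, other):
        return self.real == _real_of(other)

    def __ne__(self, other):
        return self.real != _real_of(other)

    __hash__ = None  # mutable-by-convention, ordering ignores the dual part

    def __float__(self):
        raise TypeError(
            "implicit DualScalar -> float conversion would drop the dual part; "
            "use .real explicitly"
        )

    def __repr__(self):
        return f"DualScalar({self.real!r}, {self.dual!r})"

    # chain rule hook used by the elementary functions below
    def _chain(self, value: float, deriv: float) -> "DualScalar":
        return DualScalar(value, deriv * self.dual)


class MultiDualScalar:
    """A number ``real + sum_i duals[i]*eps_i`` with ``eps_i*eps_j = 0``.

    Each dual coefficient evolves exactly as the ``dual`` field of an
    independent :class:`DualScalar` evaluation seeded with that coefficient:
    the per-coefficient floating-point operation sequence is identical, so
    results agree bitwise with ``n`` separate single-dual runs.
    """

    __slots__ = ("real", "duals")

    def __init__(self, real: Number, duals):
        self.real = float(real)
        d = np.asarray(duals, dtype=np.float64)
        if d.ndim != 1 or d.size < 1:
            raise DualShapeError("duals must be a 1-D sequence with n >= 1")
        self.duals = d

    @property
    def n(self) -> int:
        return self.duals.size

    def _check(self, other: "MultiDualScalar"):
        if self.duals.size != other.duals.size:
            raise DualShapeError(
                f"multi-dual operands carry {self.duals.size} and "
                f"{other.duals.size} dual parts"
            )

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, MultiDualScalar):
            self._check(other)
            return MultiDualScalar(self.real + other.real, self.duals + other.duals)
        if isinstance(other, _REALS):
            return MultiDualScalar(self.real + other, self.duals)
        return NotImplemented

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, MultiDualScalar):
            self._check(other)
            return MultiDualScalar(self.real - other.real, self.duals - other.duals)
        if isinstance(other, _REALS):
            return MultiDualScalar(self.real - other, self.duals)
        return NotImplemented

    def __rsub__(self, other):
        if isinstance(other, _REALS):
            return MultiDualScalar(other - self.real, -self.duals)
        return NotImplemented

    def __mul__(self, other):
        if isinstance(other, MultiDualScalar):
            self._check(other)
            return MultiDualScalar(
                self.real * other.real,
                self.real * other.duals + self.duals * other.real,
            )
        if isinstance(other, _REALS):
            return MultiDualScalar(self.real * other, self.duals * other)
        return NotImplemented

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, MultiDualScalar):
            self._check(other)
            if other.real == 0.0:
                raise ZeroDivisionError(
                    "dual division: denominator has zero real part"
                )
            return MultiDualScalar(
                self.real / other.real,
                (self.duals * other.real - self.real * other.duals)
                / (other.real * other.real),
            )
        if isinstance(other, _REALS):
            if other == 0:
                raise ZeroDivisionError("dual division: zero denominator")
            return MultiDualScalar(self.real / other, self.duals / other)
        return NotImplemented

    def __rtruediv__(self, other):
        if isinstance(other, _REALS):
            if self.real == 0.0:
                raise ZeroDivisionError(
                    "dual division: denominator has zero real part"
                )
            return MultiDualScalar(
                other / self.real, -other * self.duals / (self.real * self.real)
            )
        return NotImplemented

    def __pow__(self, p):
        if isinstance(p, _REALS):
            return _dual_power(self, float(p))
        return NotImplemented

    def __rpow__(self, base):
        if isinstance(base, _REALS):
            if base <= 0:
                raise DualDomainError(
                    f"power: non-positive base {base} with dual exponent"
                )
            v = base ** self.real
            return MultiDualScalar(v, v * math.log(base) * self.duals)
        return NotImplemented

    def __neg__(self):
        return MultiDualScalar(-self.real, -self.duals)

    def __pos__(self):
        return self

    def __abs__(self):
        s = 1.0 if self.real > 0.0 else (-1.0 if self.real < 0.0 else 0.0)
        return MultiDualScalar(abs(self.real), s * self.duals)

    # -- comparisons: real part only --------------------------------------

    def __lt__(self, other):
        return self.real < _real_of(other)

    def __le__(self, other):
        return self.real <= _real_of(other)

    def __gt__(self, other):
        return self.real > _real_of(other)

    def __ge__(self, other):
        return self.real >= _real_of(other)

    def __eq__(self, other):
        return self.real == _real_of(other)

    def __ne__(self, other):
        return self.real != _real_of(other)

    __hash__ = None

    def __float__(self):
        raise TypeError(
            "implicit MultiDualScalar -> float conversion would drop the dual "
            "parts; use .real explicitly"
        )

    def __repr__(self):
        return f"MultiDualScalar({self.real!r}, {self.duals!r})"

    def _chain(self, value: float, deriv: float) -> "MultiDualScalar":
        return MultiDualScalar(value, deriv * self.duals)


_DUALS = (DualScalar, MultiDualScalar)


def _real_of(x) -> float:
    if isinstance(x, _DUALS):
        return x.real
    if isinstance(x, _REALS):
        return float(x)
    return NotImplemented  # type: ignore[return-value]


def real_part(x) -> float:
    """Real part of a plain number or a (multi-)dual scalar."""
    return x.real if isinstance(x, _DUALS) else float(x)


def dual_part(x) -> float:
    """Dual part of a scalar; plain numbers have dual part 0."""
    if isinstance(x, DualScalar):
        return x.dual
    if isinstance(x, MultiDualScalar):
        raise TypeError("use .duals for a MultiDualScalar")
    return 0.0


def _dual_power(d, p: float):
    x = d.real
    if x > 0.0:
        return d._chain(x ** p, p * x ** (p - 1.0))
    if x == 0.0:
        if p == 0.0:
            return d._chain(1.0, 0.0)
        if p == 1.0:
            return d._chain(0.0, 1.0)
        if p > 1.0:
            return d._chain(0.0, 0.0)
        raise DualDomainError(
            f"power: derivative of x**{p} undefined at real part 0"
        )
    # negative base: integer exponents only
    if p != int(p):
        raise DualDomainError(
            f"power: negative real part {x} with non-integer exponent {p}"
        )
    return d._chain(x ** p, p * x ** (p - 1.0))


# -- elementary functions, generic over floats and dual scalars ------------


def exp(x):
    if isinstance(x, _DUALS):
        v = math.exp(x.real)
        return x._chain(v, v)
    return math.exp(x)


def log(x):
    if isinstance(x, _DUALS):
        if x.real <= 0.0:
            raise DualDomainError(f"log: non-positive real part {x.real}")
        return x._chain(math.log(x.real), 1.0 / x.real)
    return math.log(x)


def sqrt(x):
    if isinstance(x, _DUALS):
        if x.real <= 0.0:
            raise DualDomainError(
                f"sqrt: real part {x.real} not strictly positive "
                "(derivative undefined at 0)"
            )
        v = math.sqrt(x.real)
        return x._chain(v, 0.5 / v)
    return math.sqrt(x)


def sin(x):
    if isinstance(x, _DUALS):
        return x._chain(math.sin(x.real), math.cos(x.real))
    return math.sin(x)


def cos(x):
    if isinstance(x, _DUALS):
        return x._chain(math.cos(x.real), -math.sin(x.real))
    return math.cos(x)


def tanh(x):
    if isinstance(x, _DUALS):
        v = math.tanh(x.real)
        return x._chain(v, 1.0 - v * v)
    return math.tanh(x)


def power(x, p):
    """``x**p`` with a plain-real exponent ``p``."""
    if isinstance(x, _DUALS):
        return _dual_power(x, float(p))
    return float(x) ** float(p)


def maximum(a, b):
    """Larger of two scalars; ties return the first argument (and its duals)."""
    return a if _real_of(a) >= _real_of(b) else b


def minimum(a, b):
    """Smaller of two scalars; ties return the first argument."""
    return a if _real_of(a) <= _real_of(b) else b
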