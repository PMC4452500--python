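"""Closed-form operation-count model for the three engines.

Counts are in the abstract per-pixel units of the memory-bound charging
scheme: one unit per fresh image fetch or per plane-wide constant-cost
step.  With |N| = (2T+1)^2 window positions and (2B+1)^2-pixel patches:

* serial, whole image:      m * n * |N| * (2B+1)^2
* per-offset cascade:       |N| * ((2B+1)^2 + 2) + 1          per pixel
* row-cached half-window:   0.5 * |N| * (2(2B+1) + 1) + 1     per pixel

The ratio of the last two approaches 2B+1 for large windows — the headline
acceleration of the row-cached engine.  Improved counts are half-integers
and are kept as exact rationals; nothing is rounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "ComplexityReport",
    "serial_complexity",
    "conventional_complexity",
    "improved_complexity",
    "acceleration_ratio",
    "complexity_report",
]


def _check_nonneg(**kwargs: int) -> None:
    for name, v in kwargs.items():
        if not (isinstance(v, int) and v >= 0):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


def serial_complexity(m: int, n: int, T: int, B: int) -> int:
    """Total serial operation count for an m x n image: m n (2T+1)^2 (2B+1)^2."""
    _check_nonneg(T=T, B=B)
    if not (isinstance(m, int) and m >= 1 and isinstance(n, int) and n >= 1):
        raise ValueError(f"image dimensions must be positive integers, got {m!r} x {n!r}")
    return m * n * (2 * T + 1) ** 2 * (2 * B + 1) ** 2


def conventional_complexity(T: int, B: int) -> int:
    """Charged per-pixel count of the per-offset cascade: |N|((2B+1)^2 + 2) + 1."""
    _check_nonneg(T=T, B=B)
    return (2 * T + 1) ** 2 * ((2 * B + 1) ** 2 + 2) + 1


def improved_complexity(T: int, B: int) -> Fraction:
    """Charged per-pixel count of the row-cached half-window engine.

    0.5 |N| (2(2B+1) + 1) + 1, returned as an exact rational (half-integer).
    """
    _check_nonneg(T=T, B=B)
    return Fraction((2 * T + 1) ** 2 * (2 * (2 * B + 1) + 1), 2) + 1


def acceleration_ratio(T: int | None, B: int, asymptotic: bool = False) -> Fraction | int:
    """Speed-up of the row-cached engine over the per-offset cascade.

    ``asymptotic=True`` returns the large-window simplification 2B+1 (T is
    ignored and may be None); otherwise the exact ratio of the two finite
    formulas at (T, B) is returned as a rational.
    """
    _check_nonneg(B=B)
    if asymptotic:
        return 2 * B + 1
    if T is None:
        raise ValueError("T is required for the finite-window ratio")
    return Fraction(conventional_complexity(T, B)) / improved_complexity(T, B)


@dataclass(frozen=True)
class ComplexityReport:
    """All counts of the model for one (m, n, T, B) configuration."""

    m: int
    n: int
    T: int
    B: int
    serial_total: int
    conventional_per_pixel: int
    improved_per_pixel: Fraction
    ratio: Fraction
    asymptotic_ratio: int

    def as_dict(self) -> dict:
        """JSON-friendly view (rationals rendered as floats)."""
        return {
            "m": self.m,
            "n": self.n,
            "T": self.T,
            "B": self.B,
            "window_positions": (2 * self.T + 1) ** 2,
            "patch_pixels": (2 * self.B + 1) ** 2,
            "serial_total": self.serial_total,
            "conventional_per_pixel": self.conventional_per_pixel,
            "improved_per_pixel": float(self.improved_per_pixel),
            "ratio": float(self.ratio),
            "asymptotic_ratio": self.asymptotic_ratio,
        }


def complexity_report(m: int, n: int, T: int, B: int) -> ComplexityReport:
    """Evaluate every formula of the model for one configuration."""
    return ComplexityReport(
        m=m,
        n=n,
        T=T,
        B=B,
        serial_total=serial_complexity(m, n, T, B),
        conventional_per_pixel=conventional_complexity(T, B),
        improved_per_pixel=improved_complexity(T, B),
        ratio=acceleration_ratio(T, B),
        asymptotic_ratio=acceleration_ratio(None, B, asymptotic=True),
    )
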