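"""Piecewise-constant-hazard (piecewise-exponential) survival model.

Used by the synthetic generator to reproduce the early-mortality shape seen
in newly diagnosed AL amyloidosis (high hazard in the first two quarters,
then a long shallow tail) with the smallest parametric family that can match
three printed cumulative-mortality values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PiecewiseExponential"]


@dataclass(frozen=True)
class PiecewiseExponential:
    """Survival model with constant hazard on each interval.

    Parameters
    ----------
    breakpoints : sequence of float
        Interior breakpoints ``b_1 < ... < b_k`` in days from index. The
        hazard is constant on ``[0, b_1), [b_1, b_2), ..., [b_k, inf)``.
    hazards : sequence of float
        Per-day hazards, one more than there are breakpoints. All >= 0.
    """

    breakpoints: tuple[float, ...]
    hazards: tuple[float, ...]
    _edges: np.ndarray = field(init=False, repr=False, compare=False)
    _cumhaz_at_edges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        hz = np.asarray(self.hazards, dtype=float)
        if hz.size != bp.size + 1:
            raise ValueError("need exactly len(breakpoints) + 1 hazards")
        if np.any(hz < 0):
            raise ValueError("hazards must be non-negative")
        if bp.size and (np.any(np.diff(bp) <= 0) or bp[0] <= 0):
            raise ValueError("breakpoints must be positive and increasing")
        edges = np.concatenate([[0.0], bp])
        widths = np.diff(np.concatenate([edges, [np.inf]]))[:-1]
        cum = np.concatenate([[0.0], np.cumsum(hz[:-1] * widths)])
        object.__setattr__(self, "_edges", edges)
        object.__setattr__(self, "_cumhaz_at_edges", cum)

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self._edges, t, side="right") - 1
        idx = np.clip(idx, 0, len(self._edges) - 1)
        hz = np.asarray(self.hazards, dtype=float)
        return self._cumhaz_at_edges[idx] + hz[idx] * (t - self._edges[idx])

    def survival(self, t) -> np.ndarray:
        """S(t) = P(T > t)."""
        return np.exp(-self.cumulative_hazard(t))

    def cdf(self, t) -> np.ndarray:
        return 1.0 - self.survival(t)

    def integral_survival(self, a: float, b: float) -> float:
        """Exact integral of S(t) dt over [a, b] (expected person-time)."""
        if b <= a:
            return 0.0
        hz = np.asarray(self.hazards, dtype=float)
        edges = np.concatenate([self._edges, [np.inf]])
        total = 0.0
        for j in range(len(hz)):
            lo, hi = max(a, edges[j]), min(b, edges[j + 1])
            if hi <= lo:
                continue
            s_lo = self.survival(lo)
            if hz[j] == 0.0:
                total += float(s_lo) * (hi - lo)
            else:
                total += float(s_lo) * (1.0 - np.exp(-hz[j] * (hi - lo))) / hz[j]
        return total

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw event times in days by inverting the cumulative hazard.

        Returns ``inf`` where the total hazard mass is exhausted (no event).
        """
        e = rng.exponential(size=n)
        hz = np.asarray(self.hazards, dtype=float)
        edges = self._edges
        cum = self._cumhaz_at_edges
        out = np.full(n, np.inf)
        # invert within the piece where the target cumulative hazard falls
        idx = np.searchsorted(cum, e, side="right") - 1
        idx = np.clip(idx, 0, len(hz) - 1)
        ok = hz[idx] > 0
        # events can land beyond the last finite-hazard piece only if the
        # terminal hazard is positive; with hz>0 inversion is always finite
        out[ok] = edges[idx[ok]] + (e[ok] - cum[idx[ok]]) / hz[idx[ok]]
        # where the containing piece has zero hazard, push to the next piece
        # with positive hazard (or never, if none remains)
        bad = np.flatnonzero(~ok)
        for i in bad:
            j = idx[i]
            while j < len(hz) and hz[j] == 0.0:
                j += 1
            if j < len(hz):
                out[i] = edges[j] + (e[i] - cum[j]) / hz[j]
        return out

    @classmethod
    def from_cumulative_mortality(
        cls, breakpoints, targets: dict[float, float]
    ) -> "PiecewiseExponential":
        """Solve piecewise hazards so the CDF passes through printed targets.

        ``targets`` maps day -> cumulative mortality at that day. Each target
        day must coincide with a breakpoint (or extend past the last one); the
        hazard is assumed constant between consecutive target days, and the
        terminal hazard continues the last solved piece.
        """
        bp = tuple(float(b) for b in breakpoints)
        days = sorted(targets)
        logs = {0.0: 0.0}
        for d in days:
            p = targets[d]
            if not 0.0 <= p < 1.0:
                raise ValueError("cumulative mortality must be in [0, 1)")
            logs[float(d)] = -float(np.log1p(-p))
        knots = sorted(logs)
        # hazard on each inter-target span
        span_h = {}
        for a, b in zip(knots[:-1], knots[1:]):
            span_h[(a, b)] = (logs[b] - logs[a]) / (b - a)
            if span_h[(a, b)] < 0:
                raise ValueError("cumulative mortality targets must increase")
        hz = []
        edges = [0.0, *bp, np.inf]
        for lo in edges[:-1]:
            h = None
            for (a, b), v in span_h.items():
                if a <= lo < b:
                    h = v
                    break
            if h is None:  # beyond the last target: carry the last hazard
                h = span_h[(knots[-2], knots[-1])] if len(knots) > 1 else 0.0
            hz.append(h)
        return cls(bp, tuple(hz))
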