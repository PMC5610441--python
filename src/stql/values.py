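"""Value derivation for interval-creating operations.

Two value models interpret an interval's signal:

* EACH — every genomic location individually owns the interval's full
  value (e.g. normalized per-base read counts);
* TOTAL — the locations collectively own it, each receiving an equal
  share ``value / length`` (e.g. total read counts per interval).

A resulting interval's value is derived in three steps: (1) each input
interval distributes its value to its locations per the model; (2) at
every location of the resulting interval the contributions are combined
with one of the vd_* operations; (3) the resulting interval's value is
the arithmetic mean over all its locations.

The engine path (:func:`derive_values`) exploits that contributions are
piecewise constant and works on breakpoint segments;
:func:`per_location_oracle` materializes explicit per-position arrays
and is used as ground truth in tests.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .model import GenomicInterval, ValidationError, interval_length


class ValueModel(Enum):
    EACH = "each"
    TOTAL = "total"


#: aliases accepted in query text before the keyword ``model``
_MODEL_ALIASES = {"each": ValueModel.EACH, "all": ValueModel.TOTAL,
                  "total": ValueModel.TOTAL}


def parse_value_model(word: str) -> ValueModel:
    try:
        return _MODEL_ALIASES[word.lower()]
    except KeyError:
        raise ValidationError(f"unknown value model {word!r}") from None


VD_OPS = (
    "vd_sum", "vd_avg", "vd_diff", "vd_product", "vd_quotient",
    "vd_max", "vd_min", "vd_left", "vd_right",
)

_NARY = frozenset({"vd_sum", "vd_avg", "vd_product", "vd_max", "vd_min"})

#: which vd operations each interval-creating operation admits
APPLICABILITY = {
    "coalesce": _NARY,
    "discretize": _NARY,
    "project": _NARY,
    "intersectjoin": frozenset(VD_OPS),
    "exclusivejoin": frozenset({"vd_left"}),
}


def check_vd_applicable(operation: str, vd: Optional[str]) -> None:
    """Reject (operation, vd) combinations that are not defined."""
    if vd is None:
        return
    if vd not in VD_OPS:
        raise ValidationError(f"unknown value-derivation operator {vd!r}")
    allowed = APPLICABILITY[operation]
    if vd not in allowed:
        raise ValidationError(
            f"{vd} is not applicable to {operation} "
            f"(allowed: {', '.join(sorted(allowed))})"
        )


def location_share(i: GenomicInterval, model: ValueModel) -> float:
    """Step 1: per-location value of an interval under a value model."""
    if i.value is None:
        raise ValueError("null-valued interval has no location share")
    if model is ValueModel.EACH:
        return float(i.value)
    return float(i.value) / interval_length(i)


def combine_step2(op: str, values: Sequence[float]) -> Optional[float]:
    """Step 2: combine per-location contributions with a vd_* operation.

    ``values`` is ordered; for binary operations it is exactly
    ``[v1, v2]`` (first track, second track).
    """
    n = len(values)
    if op == "vd_sum":
        return float(sum(values))
    if op == "vd_avg":
        return float(sum(values)) / n
    if op == "vd_product":
        return float(math.prod(values))
    if op == "vd_max":
        return float(max(values))
    if op == "vd_min":
        return float(min(values))
    if op == "vd_diff":
        return float(values[0] - values[1])
    if op == "vd_quotient":
        if values[1] == 0:
            return None
        return float(values[0] / values[1])
    if op == "vd_left":
        return float(values[0])
    if op == "vd_right":
        return float(values[-1])
    raise ValidationError(f"unknown value-derivation operator {op!r}")


def _binary_value(
    operation: str,
    contribs: Sequence[tuple[GenomicInterval, int]],
    vd: str,
    model: ValueModel,
) -> Optional[float]:
    """intersectjoin/exclusivejoin outputs lie inside every contributor,
    so each slot's per-location share is constant over the output."""
    v1 = v2 = None
    for iv, slot in contribs:
        share = None if iv.value is None else location_share(iv, model)
        if slot == 1:
            v1 = share
        else:
            v2 = share
    if vd == "vd_left":
        return v1
    if vd == "vd_right":
        return v2
    if v1 is None or v2 is None:  # null operand: value is NULL
        return None
    return combine_step2(vd, [v1, v2])


def derive_values(
    operation: str,
    outputs: Sequence[tuple[str, int, int]],
    contributors: Sequence[Sequence[tuple[GenomicInterval, int]]],
    vd: Optional[str],
    model: Optional[ValueModel],
) -> list[Optional[float]]:
    """Derive the value of every resulting interval.

    ``outputs`` are (chr, chrstart, chrend) triples; ``contributors[k]``
    lists the (input interval, source slot) pairs overlapping output k
    (slot 1 = first/only track, slot 2 = second track).  Without a value
    clause (``vd is None``) every output gets NULL.
    """
    if vd is None:
        return [None] * len(outputs)
    check_vd_applicable(operation, vd)
    if model is None:
        model = ValueModel.EACH

    results: list[Optional[float]] = []
    for (chrom, start, end), contribs in zip(outputs, contributors):
        if operation in ("intersectjoin", "exclusivejoin"):
            results.append(_binary_value(operation, contribs, vd, model))
            continue
        # n-ary: per-location covering sets change only at breakpoints
        length = end - start + 1
        valued = [
            (max(iv.chrstart, start), min(iv.chrend, end),
             location_share(iv, model))
            for iv, _slot in contribs
            if iv.value is not None
        ]
        cuts = {start, end + 1}
        for a, b, _s in valued:
            cuts.add(a)
            cuts.add(b + 1)
        bounds = sorted(c for c in cuts if start <= c <= end + 1)
        total = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            covering = [s for (ca, cb, s) in valued if ca <= a <= cb]
            if covering:
                loc = combine_step2(vd, covering)
                if loc is None:
                    loc = 0.0
            else:
                loc = 0.0  # uncovered locations default to 0
            total += loc * (b - a)
        results.append(total / length)
    return results


_ORACLE_SPAN_LIMIT = 10**6


def per_location_oracle(
    operation: str,
    outputs: Sequence[tuple[str, int, int]],
    contributors: Sequence[Sequence[tuple[GenomicInterval, int]]],
    vd: Optional[str],
    model: Optional[ValueModel],
) -> list[Optional[float]]:
    """Reference implementation executing the three steps on explicit
    per-position arrays.  Test-only; refuses spans above 10^6 positions.
    """
    if vd is None:
        return [None] * len(outputs)
    check_vd_applicable(operation, vd)
    if model is None:
        model = ValueModel.EACH
    if sum(e - s + 1 for _c, s, e in outputs) > _ORACLE_SPAN_LIMIT:
        raise ValueError("oracle span limit exceeded")

    results: list[Optional[float]] = []
    for (chrom, start, end), contribs in zip(outputs, contributors):
        L = end - start + 1
        if operation in ("intersectjoin", "exclusivejoin"):
            v1 = np.full(L, np.nan)
            v2 = np.full(L, np.nan)
            for iv, slot in contribs:
                if iv.value is None:
                    continue
                a = max(iv.chrstart, start) - start
                b = min(iv.chrend, end) - start + 1
                (v1 if slot == 1 else v2)[a:b] = location_share(iv, model)
            if vd == "vd_left":
                loc = v1
            elif vd == "vd_right":
                loc = v2
            elif vd == "vd_sum":
                loc = v1 + v2
            elif vd == "vd_avg":
                loc = (v1 + v2) / 2.0
            elif vd == "vd_diff":
                loc = v1 - v2
            elif vd == "vd_product":
                loc = v1 * v2
            elif vd == "vd_quotient":
                with np.errstate(divide="ignore", invalid="ignore"):
                    loc = v1 / v2
                if np.any(v2 == 0):
                    results.append(None)
                    continue
            elif vd == "vd_max":
                loc = np.maximum(v1, v2)
            elif vd == "vd_min":
                loc = np.minimum(v1, v2)
            if np.any(np.isnan(loc)):
                results.append(None)
                continue
            results.append(float(loc.mean()))
            continue

        cov = np.zeros(L, dtype=int)
        ssum = np.zeros(L)
        prod = np.ones(L)
        mx = np.full(L, -np.inf)
        mn = np.full(L, np.inf)
        for iv, _slot in contribs:
            if iv.value is None:
                continue
            share = location_share(iv, model)
            a = max(iv.chrstart, start) - start
            b = min(iv.chrend, end) - start + 1
            cov[a:b] += 1
            ssum[a:b] += share
            prod[a:b] *= share
            mx[a:b] = np.maximum(mx[a:b], share)
            mn[a:b] = np.minimum(mn[a:b], share)
        covered = cov > 0
        if vd == "vd_sum":
            loc = ssum
        elif vd == "vd_avg":
            loc = np.divide(ssum, cov, out=np.zeros(L), where=covered)
        elif vd == "vd_product":
            loc = np.where(covered, prod, 0.0)
        elif vd == "vd_max":
            loc = np.where(covered, mx, 0.0)
        else:  # vd_min
            loc = np.where(covered, mn, 0.0)
        loc = np.where(covered, loc, 0.0)
        results.append(float(loc.mean()))
    return results
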