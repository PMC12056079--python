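"""Variance-minimising selection of one medicated scan per subject.

Subjects typically have several scans while on medication; the analysis
wants the cohort's treatment durations as homogeneous as possible, subject
to a minimum time on medication (12 months by default).  The selector finds
the assignment of one eligible scan per subject that minimises the
population variance of the selected durations.

The optimum has a useful structure: for the optimal assignment with mean
mu*, every subject's selected duration is the eligible candidate closest to
mu* (otherwise swapping lowers the sum of squared deviations about mu*, and
hence the variance).  It therefore suffices to sweep the candidate means:
the nearest-candidate assignment changes only at midpoints between two
candidate durations of the same subject, so enumerating all midpoint
intervals visits every potentially optimal assignment.  This is exact and
fast for any cohort size, unlike exhaustive product enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["select_scans", "duration_summary", "brute_force_select"]


def _eligible(candidates: dict, min_months: float) -> dict:
    out = {}
    for subject in sorted(candidates):
        cands = [
            (scan_id, float(d))
            for scan_id, d in candidates[subject]
            if float(d) >= min_months
        ]
        if any(float(d) < 0 for _, d in candidates[subject]):
            raise ValueError(f"subject {subject!r} has a negative duration")
        if not cands:
            raise ValueError(
                f"subject {subject!r} has no scan with >= {min_months} months "
                "on medication"
            )
        out[subject] = sorted(cands, key=lambda c: (c[1], str(c[0])))
    return out


def _variance(durations) -> float:
    return float(np.var(np.asarray(durations, float)))  # population (divide by n)


def select_scans(candidates: dict, min_months: float = 12.0) -> dict:
    """Pick one scan per subject minimising the duration variance.

    ``candidates`` maps subject -> list of ``(scan_id, duration_months)``.
    Ties in the minimal variance are broken by the lexicographically
    smallest scan-id vector over subjects sorted by id.
    """
    elig = _eligible(candidates, min_months)
    subjects = sorted(elig)

    # candidate target means: every distinct duration and every midpoint of
    # two durations of the same subject (assignment breakpoints)
    targets = set()
    for cands in elig.values():
        ds = [d for _, d in cands]
        targets.update(ds)
        targets.update((a + b) / 2.0 for a, b in itertools.combinations(ds, 2))

    best_var = np.inf
    best_assignments: list[tuple] = []
    seen = set()
    for mu in sorted(targets):
        for nudge in (-1e-9, 0.0, 1e-9):  # both sides of each breakpoint
            m = mu + nudge
            choice = []
            for subject in subjects:
                scan_id, d = min(
                    elig[subject], key=lambda c: (abs(c[1] - m), str(c[0]))
                )
                choice.append((scan_id, d))
            key = tuple(scan_id for scan_id, _ in choice)
            if key in seen:
                continue
            seen.add(key)
            var = _variance([d for _, d in choice])
            if var < best_var - 1e-12:
                best_var = var
                best_assignments = [key]
            elif abs(var - best_var) <= 1e-12:
                best_assignments.append(key)
    winner = min(best_assignments, key=lambda k: tuple(str(s) for s in k))
    return dict(zip(subjects, winner))


def brute_force_select(
    candidates: dict, min_months: float = 12.0, max_combinations: int = 10**6
) -> dict:
    """Exhaustive-enumeration reference selector (small cohorts only)."""
    elig = _eligible(candidates, min_months)
    subjects = sorted(elig)
    n_comb = int(np.prod([len(elig[s]) for s in subjects]))
    if n_comb > max_combinations:
        raise ValueError(f"{n_comb} combinations exceed the enumeration cap")
    best = None
    for combo in itertools.product(*(elig[s] for s in subjects)):
        var = _variance([d for _, d in combo])
        key = tuple(str(scan_id) for scan_id, _ in combo)
        item = (var, key, combo)
        if best is None or (var < best[0] - 1e-12) or (
            abs(var - best[0]) <= 1e-12 and key < best[1]
        ):
            best = item
    return dict(zip(subjects, (scan_id for scan_id, _ in best[2])))


def selection_durations(candidates: dict, selection: dict) -> list[float]:
    lookup = {
        subject: dict((str(s), float(d)) for s, d in cands)
        for subject, cands in candidates.items()
    }
    return [lookup[subject][str(scan)] for subject, scan in sorted(selection.items())]


def duration_summary(durations) -> dict:
    """Median, IQR (type-7 linear-interpolation quantiles), min and max."""
    d = np.asarray(list(durations), float)
    if d.size == 0:
        raise ValueError("empty selection")
    q1, q3 = np.quantile(d, [0.25, 0.75])  # numpy default = type-7
    return {
        "median": float(np.median(d)),
        "iqr": float(q3 - q1),
        "min": float(d.min()),
        "max": float(d.max()),
    }
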