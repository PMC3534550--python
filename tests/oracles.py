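"""Independent brute-force oracles used by unit and acceptance tests."""

import numpy as np


def brute_force_max_t(values, min_width=2):
    """Exhaustive O(n^2) arc scan with the pooled two-sample t."""
    n = len(values)
    arcs = []
    for i in range(n + 1):
        for j in range(i + min_width, n + 1):
            nA = j - i
            if nA > n - min_width:
                continue
            arc = values[i:j]
            comp = np.concatenate([values[:i], values[j:]])
            diff = abs(arc.mean() - comp.mean())
            ssw = ((arc - arc.mean()) ** 2).sum() + ((comp - comp.mean()) ** 2).sum()
            pooled = ssw / (n - 2) if n > 2 else 0.0
            denom = np.sqrt(pooled * (1 / nA + 1 / (n - nA)))
            if denom == 0:
                t = np.inf if diff > 1e-12 else 0.0
            else:
                t = diff / denom
            arcs.append((i, j, t))
    best_t = max(t for _, _, t in arcs)
    if np.isinf(best_t):
        tied = [a for a in arcs if np.isinf(a[2])]
    elif best_t == 0.0:
        tied = arcs
    else:
        tied = [a for a in arcs if a[2] >= best_t * (1 - 1e-10)]
    return tied[0]  # arcs enumerated in lexicographic (i, j) order


def brute_force_repeats(seq, min_unit=1, max_unit=6, min_total=8):
    """O(n^3) oracle: test every (start, unit length) for a maximal run."""
    from cnaseg.motifs import _canonical_rotation, _is_primitive

    out = set()
    n = len(seq)
    for k in range(min_unit, max_unit + 1):
        for s in range(n - 2 * k + 1):
            unit = seq[s : s + k]
            if not set(unit) <= set("ACGT") or not _is_primitive(unit):
                continue
            e = s + k
            while e < n and seq[e] in "ACGT" and seq[e] == seq[e - k]:
                e += 1
            copies, rem = divmod(e - s, k)
            if copies < 2 or copies * k < min_total:
                continue
            if s >= 1 and seq[s - 1] in "ACGT" and seq[s - 1] == seq[s - 1 + k]:
                continue  # not left-maximal
            out.add((s, _canonical_rotation(unit), copies, copies * k, rem > 0))
    return out
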