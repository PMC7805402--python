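"""Independent brute-force reference implementations used only by tests.

Deliberately naive: explicit loops over genes, lines and directions, and
textbook formulas, kept free of any code path shared with the package.
"""
import math

import numpy as np
from scipy import stats


def oracle_vote(values, pairing, theta, min_votes, alpha):
    """Per-gene vote selection by exhaustive looping.

    ``values``: DataFrame genes x samples of transformed expression;
    ``pairing``: DataFrame indexed by sample with line_id/condition.
    Returns a dict gene -> dict with votes, direction, p, rank fields.
    """
    lines = sorted(set(pairing["line_id"]), key=str)
    pair_of = {}
    for line in lines:
        basal = [s for s in pairing.index
                 if pairing.loc[s, "line_id"] == line and pairing.loc[s, "condition"] == "basal"][0]
        post = [s for s in pairing.index
                if pairing.loc[s, "line_id"] == line and pairing.loc[s, "condition"] == "post"][0]
        pair_of[line] = (basal, post)
    out = {}
    for gene in values.index:
        diffs = []
        for line in lines:
            basal, post = pair_of[line]
            diffs.append(values.loc[gene, post] - values.loc[gene, basal])
        votes = {"up": {"for": 0, "against": 0}, "down": {"for": 0, "against": 0}}
        for d in diffs:
            if d > theta:
                votes["up"]["for"] += 1
                votes["down"]["against"] += 1
            elif d < -theta:
                votes["up"]["against"] += 1
                votes["down"]["for"] += 1
        n = len(diffs)
        mean = sum(diffs) / n
        var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
        if var > 0:
            t = mean / math.sqrt(var / n)
            p_up = float(stats.t.sf(t, n - 1))
            p_down = float(stats.t.cdf(t, n - 1))
        elif mean == 0:
            t, p_up, p_down = 0.0, 0.5, 0.5
        else:
            t, p_up, p_down = float("nan"), 1.0, 1.0
        selected = {
            "up": votes["up"]["for"] >= min_votes and p_up < alpha,
            "down": votes["down"]["for"] >= min_votes and p_down < alpha,
        }
        if selected["up"] and selected["down"]:
            if votes["up"]["for"] != votes["down"]["for"]:
                direction = "up" if votes["up"]["for"] > votes["down"]["for"] else "down"
            else:
                direction = "up" if p_up <= p_down else "down"
        elif selected["up"]:
            direction = "up"
        elif selected["down"]:
            direction = "down"
        else:
            direction = "none"
        out[gene] = {
            "votes_for_up": votes["up"]["for"],
            "votes_against_up": votes["up"]["against"],
            "votes_for_down": votes["down"]["for"],
            "votes_against_down": votes["down"]["against"],
            "direction": direction,
            "p_up": p_up,
            "p_down": p_down,
        }
    # rank selected genes by ascending p in the selected direction
    sel = [(g, r["p_up"] if r["direction"] == "up" else r["p_down"])
           for g, r in out.items() if r["direction"] != "none"]
    sel.sort(key=lambda gr: (gr[1], list(values.index).index(gr[0])))
    for rank, (g, _) in enumerate(sel, start=1):
        out[g]["rank"] = rank
    return out


def oracle_otsu_classes(values):
    """Foreground set by exhaustive between-class-variance maximization.

    Tries every cut between consecutive distinct values and returns the
    boolean foreground (values above the best cut).
    """
    vals = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(vals)
    best, best_cut = -1.0, None
    for i in range(len(uniq) - 1):
        cut = (uniq[i] + uniq[i + 1]) / 2.0
        lo, hi = vals[vals <= cut], vals[vals > cut]
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        sigma = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sigma > best:
            best, best_cut = sigma, cut
    return vals > best_cut
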