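"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own query/DP code paths: ancestor
sets come from exhaustive recursive path enumeration over the raw parent
lists, Wang S-values from explicit enumeration of every upward path, and
the MICA from an argmax over the brute-force common-ancestor set.
"""

from __future__ import annotations

import math


def brute_ancestors(parents: dict[str, list[str]], term: str) -> set[str]:
    """All terms reachable by following parent links, by plain recursion."""
    out: set[str] = set()
    for p in parents.get(term, []):
        out.add(p)
        out |= brute_ancestors(parents, p)
    return out


def brute_all_paths_up(
    parent_edges: dict[str, list[tuple[str, float]]], term: str, target: str
) -> list[float]:
    """Products of edge weights along every path term -> target."""
    if term == target:
        return [1.0]
    products = []
    for parent, w in parent_edges.get(term, []):
        products.extend(w * p for p in brute_all_paths_up(parent_edges, parent, target))
    return products


def brute_wang_svalues(
    parent_edges: dict[str, list[tuple[str, float]]], term: str
) -> dict[str, float]:
    """Max path-product to every ancestor (and 1 for the term itself)."""
    anc = brute_ancestors({t: [p for p, _ in ps] for t, ps in parent_edges.items()}, term)
    out = {term: 1.0}
    for a in anc:
        out[a] = max(brute_all_paths_up(parent_edges, term, a))
    return out


def brute_mica(
    parents: dict[str, list[str]], ic: dict[str, float], ta: str, tb: str
) -> str:
    """Argmax-IC over the brute-force common-ancestor set, smallest id on ties."""
    ca = (brute_ancestors(parents, ta) | {ta}) & (brute_ancestors(parents, tb) | {tb})
    scored = sorted(t for t in ca if t in ic)
    best = scored[0]
    for t in scored[1:]:
        if ic[t] > ic[best]:
            best = t
    return best


def jaccard(t1: set[str], t2: set[str]) -> float:
    return len(t1 & t2) / len(t1 | t2)


# TOY1 worked values, each recomputed here from first principles (set
# arithmetic on the hand-propagated annotation table) rather than copied
# from the implementation.
TOY1_PROPAGATED = {
    "g1": {"A1", "A", "R"},
    "g2": {"A1", "A", "R"},
    "g3": {"A2", "A", "R"},
    "g4": {"B1", "B", "R"},
    "g5": {"C", "A", "B", "R"},
    "g6": {"B", "R"},
    "g7": {"A", "R"},
    "g8": {"R"},
}


def toy1_term_genes() -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, terms in TOY1_PROPAGATED.items():
        for t in terms:
            out.setdefault(t, set()).add(gene)
    return out


def toy1_ic() -> dict[str, float]:
    tg = toy1_term_genes()
    n = len(TOY1_PROPAGATED)
    return {t: -math.log(len(g) / n) for t, g in tg.items()}


def toy1_expected() -> dict[str, float]:
    """Every hand-derivable TOY1 number, computed by independent arithmetic."""
    ic = toy1_ic()
    tg = toy1_term_genes()
    n = len(TOY1_PROPAGATED)
    w = 0.8  # is_a contribution factor
    # Wang S-value sums for single-chain leaves A1/A2/B1: {self:1, parent:w, R:w^2}
    s_leaf_total = 1 + w + w * w
    exp = {
        "ic_A": ic["A"],
        "ic_A2": ic["A2"],
        "ic_B": ic["B"],
        "ic_root": ic["R"],
        "resnik_A1_A2": ic["A"],
        "resnik_C_B1": ic["B"],
        "schlicker_A1_A2": (2 * ic["A"] / (ic["A1"] + ic["A2"])) * (1 - len(tg["A"]) / n),
        "schlicker_A1_A1": (2 * ic["A1"] / (2 * ic["A1"])) * (1 - len(tg["A1"]) / n),
        "wang_A1_A2": (2 * w + 2 * w * w) / (2 * s_leaf_total),
        "wang_A1_B1": (2 * w * w) / (2 * s_leaf_total),
        # HRSS(A1, A2): both are their own leaves, so beta = 0
        "hrss_A1_A2": 1.0 / (1.0 + (ic["A1"] - ic["A"]) + (ic["A2"] - ic["A"])),
        "simui_g1_g3": jaccard(TOY1_PROPAGATED["g1"], TOY1_PROPAGATED["g3"]),
        "simui_g1_g4": jaccard(TOY1_PROPAGATED["g1"], TOY1_PROPAGATED["g4"]),
        "simgic_g1_g3": (
            sum(ic[t] for t in TOY1_PROPAGATED["g1"] & TOY1_PROPAGATED["g3"])
            / sum(ic[t] for t in TOY1_PROPAGATED["g1"] | TOY1_PROPAGATED["g3"])
        ),
        "to_g1_g3": float(len(TOY1_PROPAGATED["g1"] & TOY1_PROPAGATED["g3"])),
        "to_g1_g4": float(len(TOY1_PROPAGATED["g1"] & TOY1_PROPAGATED["g4"])),
        "agg_resnik_g1_g5": ic["A"],  # singleton direct sets {A1} vs {C}; MICA = A
    }
    return exp
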