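"""Congruence of interaction profiles via a hypergeometric overlap test.

Loci acting in the same pathway should interact with overlapping sets of
partner loci even when they were never called as interacting with each
other.  The congruence score of two loci is the negative log10 upper-tail
hypergeometric p-value for the number of interaction partners they share,
relative to the universe of loci tested.  The two focal loci (and any direct
interaction between them) are excluded from both partner sets and from the
universe before testing, so a single shared edge cannot inflate the score.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

_TINY = 1e-300  # floor to keep -log10 finite


@dataclass
class InteractionProfile:
    locus: str
    partners: set[str]
    universe: frozenset[str]

    def __post_init__(self):
        self.partners = set(self.partners) - {self.locus}
        if not self.partners <= set(self.universe):
            raise ValueError(f"profile {self.locus}: partners outside the universe")


@dataclass
class CongruenceScore:
    locus_a: str
    locus_b: str
    n_partners_a: int
    n_partners_b: int
    shared: int
    p_value: float
    score: float  # -log10 p


def build_profiles(
    calls: pd.DataFrame, p_cutoff: float, universe: set[str] | None = None
) -> dict[str, InteractionProfile]:
    """Symmetric partner sets from an interaction-call table.

    ``calls`` needs columns ``marker_a, marker_b, p`` (as written by the
    screen or fine-map steps); edges with ``p <= p_cutoff`` define the
    partner sets.  The universe defaults to every locus appearing in the
    table (i.e. every locus that was tested), not just those with calls.
    """
    loci = set(calls["marker_a"].astype(str)) | set(calls["marker_b"].astype(str))
    uni = frozenset(str(u) for u in universe) if universe is not None else frozenset(loci)
    partners: dict[str, set[str]] = {u: set() for u in uni}
    hits = calls[calls["p"] <= p_cutoff]
    for a, b in zip(hits["marker_a"].astype(str), hits["marker_b"].astype(str)):
        if a == b:
            continue
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return {u: InteractionProfile(u, partners.get(u, set()), uni) for u in sorted(partners)}


def congruence_score(profile_a: InteractionProfile, profile_b: InteractionProfile) -> CongruenceScore:
    """Hypergeometric upper-tail test for shared interaction partners.

    With the two focal loci removed, the universe has ``M`` loci of which
    ``|partners_b|`` are "successes"; drawing ``|partners_a|`` loci, the
    p-value is ``P(X >= shared)``.  Symmetric in the two profiles.
    """
    if profile_a.universe != profile_b.universe:
        raise ValueError("profiles must share a universe")
    a, b = profile_a.locus, profile_b.locus
    if a == b:
        raise ValueError("congruence of a locus with itself is undefined")
    if not profile_a.universe:
        raise ValueError("empty universe")
    excl = {a, b}
    pa = profile_a.partners - excl
    pb = profile_b.partners - excl
    m = len(profile_a.universe - excl)
    shared = len(pa & pb)
    p = float(hypergeom.sf(shared - 1, m, len(pb), len(pa)))
    p = min(max(p, _TINY), 1.0)
    return CongruenceScore(a, b, len(pa), len(pb), shared, p, -math.log10(p))


def congruence_table(profiles: dict[str, InteractionProfile]) -> pd.DataFrame:
    """All-pairs congruence scores as a DataFrame (one row per unordered pair)."""
    ids = sorted(profiles)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            cs = congruence_score(profiles[a], profiles[b])
            rows.append(
                {
                    "locus_a": cs.locus_a,
                    "locus_b": cs.locus_b,
                    "n_partners_a": cs.n_partners_a,
                    "n_partners_b": cs.n_partners_b,
                    "shared": cs.shared,
                    "p": cs.p_value,
                    "score": cs.score,
                }
            )
    return pd.DataFrame(
        rows, columns=["locus_a", "locus_b", "n_partners_a", "n_partners_b", "shared", "p", "score"]
    )
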