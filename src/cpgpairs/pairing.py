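"""CpG-pair construction and binarization — the core scoring representation.

Every unordered pair of differentially methylated probes becomes a feature.
Within one sample, a pair scores 1 when the lexicographically first probe's
beta value strictly exceeds the second's, otherwise 0 (ties score 0). Because
the score depends only on the within-sample ordering of two values, it is
invariant to any strictly increasing per-sample distortion — which is what
makes the representation robust to batch and platform effects.
"""

from __future__ import annotations

from itertools import combinations
from collections.abc import Sequence

import numpy as np
import pandas as pd

PairDefinition = tuple[str, str]

PAIR_SEP = "|"


def pair_id(pair: PairDefinition) -> str:
    return f"{pair[0]}{PAIR_SEP}{pair[1]}"


def parse_pair_id(pid: str) -> PairDefinition:
    a, b = pid.split(PAIR_SEP)
    return (a, b)


def build_pairs(dms_probes: Sequence[str]) -> list[PairDefinition]:
    """All unordered probe pairs in canonical (lexicographic) orientation.

    ``n`` probes yield ``n * (n - 1) / 2`` pairs.
    """
    probes = list(dms_probes)
    if len(set(probes)) != len(probes):
        raise ValueError("duplicate probe IDs in DMS list")
    if len(probes) < 2:
        raise ValueError("need at least two probes to form pairs")
    return list(combinations(sorted(probes), 2))


def score_pairs(beta: pd.DataFrame, pairs: Sequence[PairDefinition]) -> pd.DataFrame:
    """Binarize each sample over the given pairs.

    Returns a pairs x samples DataFrame of {0, 1} scores indexed by
    ``"probeA|probeB"``. The pair list is deduplicated and canonically
    ordered; a score is 1 iff beta(probe_a) > beta(probe_b) in that sample.
    """
    canon = sorted({(min(a, b), max(a, b)) for a, b in pairs})
    if not canon:
        raise ValueError("empty pair list")
    needed = sorted({p for ab in canon for p in ab})
    missing = [p for p in needed if p not in beta.index]
    if missing:
        raise ValueError(f"probes absent from beta matrix: {missing[:10]}")
    sub = beta.loc[needed]
    if sub.isna().any().any():
        raise ValueError("missing beta values encountered: impute first")
    a_idx = [a for a, _ in canon]
    b_idx = [b for _, b in canon]
    scores = (sub.loc[a_idx].to_numpy() > sub.loc[b_idx].to_numpy()).astype(np.int8)
    return pd.DataFrame(
        scores,
        index=pd.Index([pair_id(p) for p in canon], name="pair"),
        columns=beta.columns,
    )


def filter_constant_pairs(
    scores: pd.DataFrame, max_prevalence: float = 0.8
) -> pd.DataFrame:
    """Drop near-constant pairs.

    A pair is removed when its score is 1 in strictly more than
    ``max_prevalence`` of the samples, or 0 in strictly more than
    ``max_prevalence`` of the samples; such pairs carry almost no grouping
    information. A pair at exactly the threshold is retained.
    """
    frac_one = scores.mean(axis=1)
    keep = (frac_one <= max_prevalence) & (1.0 - frac_one <= max_prevalence)
    out = scores.loc[keep]
    if out.empty:
        raise ValueError("all pairs removed by the constancy filter")
    return out


def score_new_samples(
    beta: pd.DataFrame, retained_pairs: Sequence[PairDefinition | str]
) -> pd.DataFrame:
    """Score new samples (e.g. another platform) on an existing pair universe.

    Applies the identical binarization rule with no re-filtering. Raises if
    any pair probe is absent from the new platform.
    """
    pairs = [parse_pair_id(p) if isinstance(p, str) else p for p in retained_pairs]
    if not pairs:
        raise ValueError("empty retained-pair list")
    needed = sorted({p for ab in pairs for p in ab})
    missing = [p for p in needed if p not in beta.index]
    if missing:
        raise ValueError(f"probes missing from the new platform: {missing[:10]}")
    return score_pairs(beta, pairs)
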