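"""Independent brute-force oracles used by multiple test modules."""

import math


def oracle_prune(prompt, items, embedder, percentile, floor, volume):
    """Reference pruning: sort each group's similarities, take the
    linear-interpolation percentile, keep strictly-greater values that
    also clear the floor, pool, rank, cap.

    ``items`` is a list of ``(text, entity_id)``.  Returns
    ``[(text, similarity), ...]`` in final order.
    """
    texts = [text for text, _ in items]
    vectors = embedder.embed([prompt] + texts)
    prompt_vec = vectors[0]
    sims = [float(v @ prompt_vec) for v in vectors[1:]]

    groups = {}
    for (text, entity), sim in zip(items, sims):
        groups.setdefault(entity, []).append((text, sim))

    kept = []
    for members in groups.values():
        ordered = sorted(sim for _, sim in members)
        n = len(ordered)
        if percentile is None:
            threshold = -math.inf
        elif n == 1:
            threshold = ordered[0]
        else:
            position = percentile / 100.0 * (n - 1)
            low = math.floor(position)
            frac = position - low
            high = min(low + 1, n - 1)
            threshold = ordered[low] + frac * (ordered[high] - ordered[low])
        for text, sim in members:
            if sim > threshold and sim >= floor:
                kept.append((text, sim))

    kept.sort(key=lambda pair: (-pair[1], pair[0]))
    return kept[:volume]
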