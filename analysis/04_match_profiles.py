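"""Match temporal activation profiles across the two movement strategies.

Constrained k-means++: the number of clusters grows until every profile
correlates >= 0.9 with its centroid and no cluster holds two profiles of the
same strategy. Singleton clusters mark strategy-specific synergies.
"""

from common import EXTRACTION_DIR, MATCHING_DIR, SEED, TASK

from synergykit import io as skio
from synergykit.matching import find_min_valid_k, robustness_check


def main():
    movement, floor = TASK
    prefix = f"{movement}_{floor}_"
    profiles = []
    for p in sorted(EXTRACTION_DIR.glob(f"{prefix}*_temporal.json")):
        model = skio.read_model_json(p)
        strategy = p.stem[len(prefix):-len("_temporal")]
        for j in range(model.trial_independent.shape[1]):
            profiles.append((strategy, model.trial_independent[:, j]))

    sol = find_min_valid_k(profiles, seed=SEED)
    agreement = robustness_check(profiles, repeats=10, seed=SEED)
    MATCHING_DIR.mkdir(parents=True, exist_ok=True)
    skio.write_json(
        MATCHING_DIR / "clusters.json",
        dict(
            task=f"{movement}|{floor}", k=sol.k,
            assignments=sol.assignments, strategies=sol.strategies,
            correlations=sol.correlations,
            singletons=sol.singleton_clusters,
            chronological_order=sol.order, agreement=agreement,
        ),
    )
    shared = sol.k - len(sol.singleton_clusters)
    print(
        f"{movement}|{floor}: {sol.k} clusters "
        f"({shared} shared across strategies, "
        f"{len(sol.singleton_clusters)} strategy-specific); "
        f"assignment agreement over 10 repeats: {agreement:.0%}"
    )


if __name__ == "__main__":
    main()
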