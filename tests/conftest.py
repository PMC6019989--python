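import numpy as np
import pytest

from gestloss import GeneratorConfig, Outcome, PregnancyRecord, exclude_unknown_ga, generate

#: Published interval tallies used across tests: risk-set sizes and event
#: counts for the 6,0-7,6 / 8,0-11,6 / 12,0-19,6 week windows.
RISK_SET_SIZES = (2775, 10452, 19200)
MISC_COUNTS = (307, 1019, 1114)
MTP_COUNTS = (112, 456, 727)
MISC_RATES = (115.3, 101.9, 60.3)
MTP_RATES = (45.4, 48.3, 40.2)
MISC_DENOMS = (2663, 9996, 18473)
MTP_DENOMS = (2468, 9433, 18086)


@pytest.fixture(scope="session")
def default_registry():
    """Default-condition synthetic registry (n=30,000) with its ground truth."""
    records, truth = generate(GeneratorConfig(), seed=0)
    return records, truth


@pytest.fixture(scope="session")
def default_kept(default_registry):
    records, _ = default_registry
    kept, _ = exclude_unknown_ga(records)
    return kept


def random_small_registry(rng: np.random.Generator, n: int) -> list[PregnancyRecord]:
    """Adversarial small registries for oracle comparisons: enrollment and
    outcome days concentrated on and around interval boundaries."""
    edge_days = [41, 42, 43, 55, 56, 57, 83, 84, 85, 139, 140, 141]
    records = []
    for i in range(n):
        enroll = int(rng.choice(edge_days + [30, 50, 70, 100, 120]))
        kind = rng.random()
        if kind < 0.35:
            outcome = Outcome.MISCARRIAGE
            day = int(rng.choice([d for d in edge_days if d < 140]))
        elif kind < 0.6:
            outcome = Outcome.MTP
            day = int(rng.choice([d for d in edge_days if d < 140] + [150]))
        elif kind < 0.7:
            outcome = Outcome.STILLBIRTH
            day = int(rng.integers(140, 290))
        else:
            outcome = Outcome.LIVEBIRTH
            day = int(rng.integers(200, 295))
        if day < enroll:
            enroll = max(0, day - 1)
        records.append(
            PregnancyRecord(
                woman_id=f"S{i:04d}",
                cluster_id=f"C{int(rng.integers(1, 4))}",
                outcome=outcome,
                enroll_ga_days=None if rng.random() < 0.05 else enroll,
                outcome_ga_days=day,
                neonatal_death_by_28d=(bool(rng.random() < 0.03)
                                       if outcome == Outcome.LIVEBIRTH else None),
            )
        )
    return records
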