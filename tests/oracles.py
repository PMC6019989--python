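"""Independent brute-force oracles: per-woman scans with plain Python loops.

Deliberately written without the package's vectorized machinery so they can
serve as a second, independent route to risk-set membership, event counts and
competing-exclusion denominators.
"""

from gestloss.registry_model import Outcome


def oracle_risk_set_ids(records, interval):
    ids = []
    for r in records:
        if r.enroll_ga_days is None or r.enroll_ga_days >= interval.start_days:
            continue
        if (
            r.outcome in (Outcome.MISCARRIAGE, Outcome.MTP)
            and r.outcome_ga_days is not None
            and r.outcome_ga_days < interval.start_days
        ):
            continue
        ids.append(r.woman_id)
    return set(ids)


def oracle_event_count(records, interval, event):
    members = oracle_risk_set_ids(records, interval)
    n = 0
    for r in records:
        if r.woman_id not in members:
            continue
        if r.outcome == event and r.outcome_ga_days is not None:
            if interval.start_days <= r.outcome_ga_days < interval.end_days:
                n += 1
    return n


def oracle_rate(records, interval, event):
    """(numerator, denominator, per-1000 rate) with competing-event exclusion."""
    n_at_risk = len(oracle_risk_set_ids(records, interval))
    competing = Outcome.MTP if event == Outcome.MISCARRIAGE else Outcome.MISCARRIAGE
    num = oracle_event_count(records, interval, event)
    den = n_at_risk - oracle_event_count(records, interval, competing)
    return num, den, 1000.0 * num / den
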