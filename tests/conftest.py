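import numpy as np

from actireid.cohort import Cohort, DemographicProfile, MinuteSeries


def make_profile(**overrides) -> DemographicProfile:
    fields = dict(
        age_years=40,
        sex="male",
        education="<=HS",
        income="<25k",
        race_ethnicity="White",
        birth_country="US",
    )
    fields.update(overrides)
    return DemographicProfile(**fields)


def make_series(record_id: str, rng=None, n_days: int = 7) -> MinuteSeries:
    rng = rng or np.random.default_rng(abs(hash(record_id)) % 2**31)
    counts = rng.integers(0, 500, size=(n_days, 1440))
    return MinuteSeries(record_id, counts, tuple(range(1, n_days + 1)))


def make_cohort(n: int = 3, seed: int = 0, **profile_overrides) -> Cohort:
    rng = np.random.default_rng(seed)
    parts = {}
    for i in range(n):
        rid = f"r{i:04d}"
        parts[rid] = (make_profile(**profile_overrides), make_series(rid, rng))
    ages = [p.age_years for p, _ in parts.values()]
    label = "adult" if all(a >= 18 for a in ages) else "mixed"
    return Cohort(parts, label)
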