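"""Simulate a check-in corpus and reduce it to daily activity sequences.

Generates two weeks of synthetic check-ins for 80 users, assigns the seven
activity types through the packaged category map, applies the cleaning
filters (min 10 check-ins per POI, min 10 minutes between a user's kept
check-ins), segments at the 5 AM wall-clock boundary, and merges runs of
repeated types into daily sequences.
"""
from actmotifs import (SimulationConfig, assign_activity_types,
                       default_category_map, generate_checkins, preprocess)

config = SimulationConfig(n_users=80, days=14, seed=42)
records = generate_checkins(config)
print(f"simulated check-ins:        {len(records)}")

records = assign_activity_types(records, default_category_map())
sequences, stats = preprocess(records)

print(f"user-days with check-ins:   {stats.n_day_groups}")
print(f"daily sequences (len >= 2): {stats.n_sequences} "
      f"from {stats.n_users} users")
print(f"length histogram:           {stats.length_histogram}")
print(f"sequences of length >= 4:   {stats.n_with_min_length(4)}")
# Most days collapse to one or two merged activities; only the long minority
# of days can host patterns with three or more transitions.
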