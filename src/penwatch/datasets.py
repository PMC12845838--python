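"""Published reference measurements for the analytics routines.

Values transcribed from a six-day, three-animal monitoring study of
singly-housed Goettingen minipigs (12 h lights-on days, 06:30-18:30, dry
feedings around 07:00 and 13:00).  They let every behavioral summary be
recomputed offline: per-hour event counts and mean durations aggregated
over all 18 pig-days, and the per-day event counts, total drinking times
and duration statistics for each animal.
"""

from __future__ import annotations

import pandas as pd

#: Aggregate per-clock-hour drinking event counts over all 18 pig-days.
HOURLY_EVENT_COUNTS: dict[int, int] = {
    6: 20, 7: 25, 8: 49, 9: 51, 10: 52, 11: 41, 12: 42,
    13: 42, 14: 69, 15: 93, 16: 82, 17: 33, 18: 13,
}

#: Mean drinking-event duration (seconds) per clock hour, same aggregation.
HOURLY_MEAN_DURATION_S: dict[int, float] = {
    6: 13.7, 7: 42.6, 8: 58.6, 9: 40.1, 10: 36.7, 11: 28.5, 12: 30.9,
    13: 34.6, 14: 56.0, 15: 38.6, 16: 48.1, 17: 53.3, 18: 9.2,
}

#: Daily drinking-event counts per animal (six consecutive healthy days).
DAILY_EVENT_COUNTS: dict[str, list[int]] = {
    "pig1": [29, 35, 44, 64, 55, 59],
    "pig2": [15, 10, 15, 12, 14, 20],
    "pig3": [22, 25, 24, 27, 73, 69],
}

#: Total daily drinking time in seconds per animal, same days.
DAILY_TOTAL_S: dict[str, list[float]] = {
    "pig1": [2133.4, 2272.2, 2285.2, 2828.5, 2327.3, 2041.9],
    "pig2": [240.5, 145.5, 244.6, 151.7, 231.7, 261.6],
    "pig3": [2108.3, 2235.6, 2388.9, 560.5, 1563.7, 1345.6],
}

#: Mean event duration (s) per pig-day.
DAILY_MEAN_S: dict[str, list[float]] = {
    "pig1": [73.6, 64.6, 51.9, 44.2, 42.3, 34.6],
    "pig2": [16.0, 14.5, 16.3, 12.6, 16.6, 13.1],
    "pig3": [95.8, 89.4, 99.5, 20.8, 21.4, 19.5],
}


def load_hourly_reference() -> pd.DataFrame:
    """Hourly summary frame (counts, mean and total durations) from the study."""
    from penwatch.analytics import hourly_from_counts
    return hourly_from_counts(HOURLY_EVENT_COUNTS, HOURLY_MEAN_DURATION_S)


def load_daily_reference() -> pd.DataFrame:
    """Long-format pig-day table: pig, day, events, total_s, mean_s."""
    rows = []
    for pig in DAILY_EVENT_COUNTS:
        for day in range(6):
            rows.append({
                "pig": pig, "day": day + 1,
                "events": DAILY_EVENT_COUNTS[pig][day],
                "total_s": DAILY_TOTAL_S[pig][day],
                "mean_s": DAILY_MEAN_S[pig][day],
            })
    return pd.DataFrame(rows)
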