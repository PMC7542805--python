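"""Two-month season definitions with one-month gaps.

Seasons are fixed two-calendar-month windows: spring = March-April,
summer = June-July, autumn = September-October, winter = December-January.
The months in between (February, May, August, November) belong to no season;
the gap absorbs phenological variation in the timing of breeding and
migration.  Winter straddles New Year and is anchored to the year of its
December: a fix on 1 January belongs to the winter of the previous calendar
year.
"""

from __future__ import annotations

SEASONS = ("spring", "summer", "autumn", "winter")

#: season -> calendar months (winter: December of the cycle year, then January)
SEASON_MONTHS: dict[str, tuple[int, int]] = {
    "spring": (3, 4),
    "summer": (6, 7),
    "autumn": (9, 10),
    "winter": (12, 1),
}

_MONTH_TO_SEASON = {3: "spring", 4: "spring", 6: "summer", 7: "summer",
                    9: "autumn", 10: "autumn", 12: "winter", 1: "winter"}

#: season pairs as (first season, second season, cycle-year offset of the
#: second season).  An annual cycle Y runs summer(Y) -> autumn(Y) ->
#: winter(Y, Dec Y - Jan Y+1) -> spring(Y, Mar-Apr Y+1); the cycle closes
#: with spring(Y) -> summer(Y+1), hence the offset 1 on the last pair.
CONSECUTIVE_PAIRS = (
    ("summer", "autumn", 0),
    ("autumn", "winter", 0),
    ("winter", "spring", 0),
    ("spring", "summer", 1),
)

#: all six unordered pairs among the four seasons of one cycle
ALL_PAIRS = (
    ("summer", "autumn", 0), ("summer", "winter", 0), ("summer", "spring", 0),
    ("autumn", "winter", 0), ("autumn", "spring", 0), ("winter", "spring", 0),
)


def season_of_month(month: int) -> str | None:
    """Season name for a calendar month, or None for a gap month."""
    return _MONTH_TO_SEASON.get(month)


def cycle_year(year: int, month: int) -> int:
    """Annual-cycle year of a fix.

    The cycle is anchored at summer: June-October fixes belong to their
    calendar year, December to the year of that December, and January
    (winter's second month) and March-April (spring, which follows that
    cycle's winter) roll back to the previous calendar year.
    """
    return year - 1 if month in (1, 3, 4) else year


def season_pairs(pairing: str) -> tuple[tuple[str, str, int], ...]:
    if pairing == "consecutive":
        return CONSECUTIVE_PAIRS
    if pairing == "all":
        return ALL_PAIRS
    raise ValueError(f"unknown pairing mode: {pairing!r}")
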