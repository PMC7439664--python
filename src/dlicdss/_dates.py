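"""Calendar-month date arithmetic shared engine-wide.

All freshness windows (the 6-month laboratory lookback, the 9-month
pregnancy-alert expiry, monitoring repeat intervals) are defined in
calendar months.  Every module goes through these helpers so boundary
semantics stay consistent.
"""

from __future__ import annotations

import datetime as dt

from dateutil.relativedelta import relativedelta


def as_datetime(value: dt.date | dt.datetime) -> dt.datetime:
    """Coerce a date to a timezone-naive datetime at midnight."""
    if isinstance(value, dt.datetime):
        return value
    return dt.datetime(value.year, value.month, value.day)


def add_months(when: dt.date | dt.datetime, months: int) -> dt.datetime:
    return as_datetime(when) + relativedelta(months=months)


def within_window(
    observed_at: dt.date | dt.datetime,
    as_of: dt.date | dt.datetime,
    window_months: int,
) -> bool:
    """Half-open calendar window (as_of - window, as_of].

    A result exactly ``window_months`` old is excluded; a result stamped
    exactly at ``as_of`` is included.  Future-dated results are excluded.
    """
    t = as_datetime(observed_at)
    end = as_datetime(as_of)
    start = add_months(end, -window_months)
    return start < t <= end


def age_years(birth_date: dt.date, as_of: dt.date | dt.datetime) -> float:
    """Age in fractional years at an explicit as-of instant (never wall clock)."""
    ref = as_of.date() if isinstance(as_of, dt.datetime) else as_of
    whole = ref.year - birth_date.year - (
        (ref.month, ref.day) < (birth_date.month, birth_date.day)
    )
    anniversary = _safe_replace_year(birth_date, birth_date.year + whole)
    next_anniversary = _safe_replace_year(birth_date, birth_date.year + whole + 1)
    span = (next_anniversary - anniversary).days
    frac = (ref - anniversary).days / span if span else 0.0
    return whole + frac


def _safe_replace_year(d: dt.date, year: int) -> dt.date:
    try:
        return d.replace(year=year)
    except ValueError:  # Feb 29 on a non-leap year
        return d.replace(year=year, day=28)
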