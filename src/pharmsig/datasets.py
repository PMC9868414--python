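"""Access to the packaged example data.

Ships three kinds of files under ``pharmsig/data``:

* ``example_vocabulary.yaml`` — an antihypertensive drug vocabulary
  fixture (canonical name, class, synonyms) covering eleven drug
  classes from loop diuretics through fixed-dose compound preparations.
* ``example_events.yaml`` — the five urate-related adverse events, each
  defined by one MedDRA Preferred Term.
* ``published_tables/*.csv`` — transcriptions of published FAERS
  disproportionality signal tables for these drugs and events (per-event
  N / PRR / chi-squared rows, plus the demographic overview counts),
  used for regression-testing the classification, counting and overlap
  logic against printed results.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from pharmsig.screening import ScreenResult, results_from_table
from pharmsig.vocabulary import DrugVocabulary, EventDefinition, load_vocabulary, load_events

#: event label -> published signal-table file stem
PUBLISHED_EVENTS = {
    "hyperuricaemia": "hyperuricaemia",
    "gout": "gout",
    "gouty arthritis": "gouty_arthritis",
    "gouty tophus": "gouty_tophus",
    "urate nephropathy": "urate_nephropathy",
}


def _data_dir() -> Path:
    return Path(resources.files("pharmsig") / "data")


def example_vocabulary_path() -> Path:
    return _data_dir() / "example_vocabulary.yaml"


def example_events_path() -> Path:
    return _data_dir() / "example_events.yaml"


def published_table_path(event_label: str) -> Path:
    try:
        stem = PUBLISHED_EVENTS[event_label]
    except KeyError:
        raise KeyError(
            f"no published table for event {event_label!r}; "
            f"known events: {sorted(PUBLISHED_EVENTS)}"
        ) from None
    return _data_dir() / "published_tables" / f"{stem}.csv"


def load_example_vocabulary() -> DrugVocabulary:
    return load_vocabulary(example_vocabulary_path())


def load_example_events() -> list[EventDefinition]:
    return load_events(example_events_path())


def load_published_screen() -> ScreenResult:
    """Published signal tables as a :class:`ScreenResult`.

    Classifications are recomputed from the printed N / PRR / chi2
    values via the Evans criterion, so counting and overlap logic can
    be regression-tested against the published summaries.
    """
    per_event = {
        label: results_from_table(published_table_path(label), label)
        for label in PUBLISHED_EVENTS
    }
    return ScreenResult(per_event=per_event)


def load_overview_counts() -> pd.DataFrame:
    """Published overview counts (event, breakdown, stratum, count)."""
    return pd.read_csv(_data_dir() / "published_tables" / "overview_counts.csv")
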