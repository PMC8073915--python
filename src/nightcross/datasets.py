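"""Published per-bird migration summaries for eleven GPS-tracked purple martins.

Small reference tables from the spring-migration tracking of *Progne
subis* to Florida, Texas and Manitoba breeding colonies: per-bird counts
of day and night flights over water, and total migration distances.
They let the group-summary arithmetic (means, standard errors,
percentages) be recomputed from the per-bird values.

A missing count (the bird made no flights in that cell) is NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_WATER_FLIGHTS = [
    # bird_id, breeding group, day flights over water, night flights over water
    ("1598", "florida", 1, 2),
    ("1602", "florida", 3, 2),
    ("2810", "texas", 1, 2),
    ("48041", "texas", 2, 2),
    ("48042", "texas", 1, 1),
    ("48045", "texas", 2, 2),
    ("48046", "texas", 3, 3),
    ("48051", "texas", 1, np.nan),
    ("48052", "texas", 3, 2),
    ("48794", "texas", 1, 1),
    ("2177", "manitoba", 3, 2),
]

_TOTALS_KM = [
    ("1598", "florida", 4859.26),
    ("1602", "florida", 6201.80),
    ("2810", "texas", 3907.73),
    ("48041", "texas", 7138.05),
    ("48042", "texas", 3620.68),
    ("48045", "texas", 8079.28),
    ("48046", "texas", 6784.23),
    ("48051", "texas", 8397.53),
    ("48052", "texas", 7515.37),
    ("48794", "texas", 4152.84),
    ("2177", "manitoba", 7611.80),
]


def water_flight_counts() -> pd.DataFrame:
    """Day/night flights over water per bird (11 birds)."""
    return pd.DataFrame(
        _WATER_FLIGHTS, columns=["bird_id", "group", "n_day_water", "n_night_water"]
    )


def migration_totals() -> pd.DataFrame:
    """Total spring migration distance (km) per bird."""
    return pd.DataFrame(_TOTALS_KM, columns=["bird_id", "group", "total_km"])
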