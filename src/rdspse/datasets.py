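"""Published summary tables from the Armenia biobehavioral surveys.

The raw RDS microdata from the 2012/2014/2016 Armenia surveys were never
deposited, but the published summary values — expert prior ranges, SS-PSE
posterior quantiles, and the comparison estimators — are themselves inputs
for the assessment and comparison machinery.  ``armenia_sspse_table()``
holds the prior/posterior summary per population-city-year;
``armenia_comparison_table()`` the method comparison (NaN = value not
collected or model would not converge).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_SSPSE_ROWS = [
    # population, city, year, expert_low, prior_median, expert_high,
    #   q5, q25, median, q75, q95, assessment
    ("FSW", "Yerevan", 2012, 1500, 3143, 9900, 1243, 2235, 3734, 6975, 16599, "Great"),
    ("FSW", "Yerevan", 2014, 1500, 3143, 9900, 397, 421, 445, 469, 542, "Bad"),
    ("FSW", "Yerevan", 2016, 1500, 3143, 9900, 784, 1340, 2090, 4169, 12924, "Okay"),
    ("FSW", "Gyumri", 2016, 165, 351, 1089, 126, 152, 171, 217, 340, "Okay"),
    ("FSW", "Vanadzor", 2016, 115, 239, 759, 133, 164, 205, 280, 551, "Great"),
    ("MSM", "Yerevan", 2012, 2420, 4202, 6667, 943, 1550, 2407, 4335, 14296, "Bad"),
    ("MSM", "Yerevan", 2014, 2420, 4202, 6667, 836, 1407, 2299, 4477, 17973, "Bad"),
    ("MSM", "Yerevan", 2016, 2420, 4202, 6667, 871, 1121, 1550, 2264, 4870, "Bad"),
    ("MSM", "Gyumri", 2016, 176, 306, 485, 127, 176, 249, 409, 974, "Okay"),
    ("MSM", "Vanadzor", 2016, 123, 214, 339, 323, 506, 666, 836, 993, "Bad"),
    ("PWID", "Yerevan", 2012, 1667, 5842, 14473, 1196, 2041, 3236, 5823, 17117, "Good"),
    ("PWID", "Yerevan", 2014, 1667, 5842, 14473, 1196, 2091, 3435, 3569, 19008, "Good"),
    ("PWID", "Yerevan", 2016, 1667, 5842, 14473, 698, 947, 1245, 2091, 6072, "Bad"),
    ("PWID", "Gyumri", 2016, 167, 584, 1446, 197, 354, 596, 1141, 2960, "Great"),
    ("PWID", "Vanadzor", 2016, 117, 409, 1013, 201, 318, 477, 812, 1775, "Great"),
]

_NA = np.nan
_COMPARISON_ROWS = [
    # population, city, year, expert_low, expert_median, expert_high,
    #   object_multiplier, service_multiplier, wisdom_of_crowds,
    #   sspse_no_visibility (NaN = would not converge), sspse_visibility
    ("FSW", "Yerevan", 2012, 1500, 3143, 9900, _NA, _NA, _NA, 2041, 3734),
    ("FSW", "Yerevan", 2014, 1500, 3143, 9900, _NA, _NA, _NA, 469, 445),
    ("FSW", "Yerevan", 2016, 1500, 3143, 9900, 571, 1283, 1615, _NA, 2090),
    ("FSW", "Gyumri", 2016, 165, 351, 1089, 150, 92, 196, 277, 171),
    ("FSW", "Vanadzor", 2016, 115, 239, 759, 204, 156, 67, 275, 205),
    ("MSM", "Yerevan", 2012, 2420, 4202, 6667, _NA, _NA, _NA, _NA, 2407),
    ("MSM", "Yerevan", 2014, 2420, 4202, 6667, _NA, _NA, _NA, _NA, 2299),
    ("MSM", "Yerevan", 2016, 2420, 4202, 6667, 749, 8300, 11900, 1121, 1550),
    ("MSM", "Gyumri", 2016, 176, 306, 485, 3659, _NA, 138, 168, 249),
    ("MSM", "Vanadzor", 2016, 123, 214, 339, 150, _NA, 40, _NA, 666),
    ("PWID", "Yerevan", 2012, 1667, 5842, 14473, _NA, _NA, _NA, 1245, 3236),
    ("PWID", "Yerevan", 2014, 1667, 5842, 14473, _NA, _NA, _NA, 1743, 3435),
    ("PWID", "Yerevan", 2016, 1667, 5842, 14473, 9000, _NA, 19342, 997, 1245),
    ("PWID", "Gyumri", 2016, 167, 584, 1446, 3000, 6800, 26, _NA, 596),
    ("PWID", "Vanadzor", 2016, 117, 409, 1013, 3000, 7000, 198, _NA, 477),
]

#: (population, city, year) rows whose no-visibility SS-PSE would not
#: converge, as distinct from values simply not collected.
NO_VISIBILITY_NO_FIT = [
    ("FSW", "Yerevan", 2016),
    ("MSM", "Yerevan", 2012),
    ("MSM", "Yerevan", 2014),
    ("MSM", "Vanadzor", 2016),
    ("PWID", "Gyumri", 2016),
    ("PWID", "Vanadzor", 2016),
]


def armenia_sspse_table() -> pd.DataFrame:
    """Expert prior values and imputed-visibility SS-PSE posterior quantiles
    for the 15 Armenia datasets.  ``expert_low``/``expert_high`` are the
    minimum of the expert lows and the maximum of the expert highs;
    ``prior_median`` the average of the two expert medians."""
    return pd.DataFrame(
        _SSPSE_ROWS,
        columns=["population", "city", "year", "expert_low", "prior_median",
                 "expert_high", "q5", "q25", "median", "q75", "q95", "assessment"],
    )


def armenia_comparison_table() -> pd.DataFrame:
    """Point estimates of the comparison methods beside the SS-PSE medians
    for the 15 Armenia datasets."""
    return pd.DataFrame(
        _COMPARISON_ROWS,
        columns=["population", "city", "year", "expert_low", "expert_median",
                 "expert_high", "object_multiplier", "service_multiplier",
                 "wisdom_of_crowds", "sspse_no_visibility", "sspse_visibility"],
    )
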