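{
  "table1": {
    "source": "regulatory breakpoint grid (GB 3095-2012 scheme) as used by the Hebei study",
    "notes": [
      "O3 has no breakpoints above sub-index 300; blank cells are intentional."
    ]
  },
  "table2": {"source": "AQI banding (level, category, color)", "notes": []},
  "table3": {
    "source": "connection-degree safety intervals",
    "notes": [
      "Printed intervals share endpoints; this package assigns boundary values to the higher (safer) grade."
    ]
  },
  "table4": {
    "source": "Hebei annual IAQI and AQI, 2013-2020",
    "notes": [
      {
        "cell": "2016 PM2.5",
        "value": 137.5,
        "inconsistent": true,
        "note": "Breaks the monotone decline of the underlying concentrations and disagrees with the 2016 PM2.5 connection number of table7; carried verbatim."
      }
    ]
  },
  "table5": {
    "source": "ln(R/S) trace per pollutant and for AQI, spans k=2..8",
    "notes": [
      {
        "cells": "k=3..7, all columns",
        "inconsistent": true,
        "note": "Intermediate-span values are not exactly reproducible under any single window policy (anchored, partition, sliding); differences reach ~0.08. The k=2 row (analytically 0) and the k=8 anchored value are reproducible."
      }
    ]
  },
  "table6": {
    "source": "Hurst index and R^2 per column, OLS on the table5 log pairs",
    "notes": []
  },
  "table7": {
    "source": "five-element connection numbers per pollutant and year",
    "notes": [
      {
        "cell": "O3 2015",
        "inconsistent": true,
        "note": "Printed as a bare capital lambda; encoded as a pure-lambda term (b1 = 1)."
      },
      {
        "cells": "PM2.5 2017-2020",
        "inconsistent": true,
        "note": "Identical entries 0.25 + 0.75 lambda despite differing table4 IAQI values; underlying concentrations were never printed. Carried verbatim."
      }
    ]
  },
  "table8": {
    "source": "comprehensive connection numbers, degrees and trend labels",
    "notes": [
      {
        "cell": "2013 b2",
        "value": 0.325,
        "inconsistent": true,
        "note": "Equal-weight averaging of table7's 2013 entries gives b2 = 0.2788, which also restores a+b1+b2 = 1; carried verbatim."
      },
      {
        "cell": "2015 b1",
        "value": 0.627,
        "inconsistent": true,
        "note": "Equal-weight averaging of table7's 2015 entries gives b1 = 0.635; carried verbatim."
      },
      {
        "cell": "degree column",
        "note": "Headed 'fourth-order partial relation number' in the source but numerically equal to the evaluated comprehensive degree a + 0.5 b1 - 0.5 b3 - c for every year, not to the order-4 adjacent-ratio recursion."
      },
      {
        "cell": "2013 trend (fourth-order column)",
        "inconsistent": true,
        "note": "First year carries a label although no prior year exists to compare against."
      }
    ]
  }
}
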