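"""Published QTL allele-class means and relative-performance values used
as a verification fixture for the RP computation.

``exact`` rows reproduce the printed RP to two decimals from the printed
class means; ``rounded`` rows are internally consistent only up to the
half-ULP pre-rounding of the printed means (the printed RP was computed
from unrounded means), so they are checked against the RP interval
attainable by perturbing each printed mean by +-0.005.
"""

# qtl, (major, het, minor) class means, printed RP %
EXACT_ROWS = [
    ("QRdw.2H", (7.85, 7.15, 5.60), 40.18),
    ("QRdw.3H", (5.90, 6.70, 8.39), 42.20),
    ("QRl.5H", (46.00, 47.50, 48.67), 5.80),
    ("QRl.7H", (47.33, 45.75, 44.00), 7.57),
    ("QSdw.2H.b", (17.61, 19.56, 22.85), 29.76),
    ("QTil.1H", (10.00, 14.50, 15.00), 50.00),
    ("QTil.2H", (11.00, 19.50, 14.00), 77.27),
    ("QTil.7H", (11.00, 13.00, 20.00), 81.82),
    ("QRS.3H", (0.36, 0.81, 0.37), 125.00),
    ("QRS.4H", (0.34, 0.36, 0.42), 23.53),
    ("QRS.5H", (0.35, 0.38, 0.55), 57.14),
    ("QRS.7H", (0.34, 0.39, 0.39), 14.71),
]

ROUNDED_ROWS = [
    ("QRdw.1H", (5.84, 4.09, 7.48), 82.76),
    ("QRdw.5H", (6.96, 7.52, 9.48), 36.16),
    ("QSdw.2H.a", (20.80, 26.62, 15.88), 67.65),
    ("QSdw.4H", (21.24, 16.83, 16.42), 29.32),
    ("QRS.2H", (0.42, 0.38, 0.30), 38.33),
]


def rp_rounding_interval(means, ulp=0.005):
    """RP range attainable when each printed mean may be off by +-ulp."""
    lo_m, hi_m = min(means), max(means)
    lo_rp = 100.0 * (hi_m - ulp - (lo_m + ulp)) / (lo_m + ulp)
    hi_rp = 100.0 * (hi_m + ulp - (lo_m - ulp)) / (lo_m - ulp)
    return lo_rp, hi_rp
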