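"""Published CLOD benchmark values used as verification fixtures.

These are printed results from the original CLOD compensating-material
study: measured doses and dose differences for the accuracy comparison
(four materials x two scan modes x two delivered doses) and the
scan-uniformity coefficients of variation. They serve as desk-check inputs
for the metrics module, never as fitted or tuned quantities.
"""

from __future__ import annotations

__all__ = ["ACCURACY_TABLE", "UNIFORMITY_TABLE", "MATERIALS", "MODES"]

MATERIALS = ("air", "DS", "SC", "OG")
MODES = ("transmission", "reflective")

#: Accuracy benchmark: (material, mode, delivered cGy) ->
#: (measured dose cGy, printed dose difference %).
ACCURACY_TABLE: dict[tuple[str, str, float], tuple[float, float]] = {
    ("air", "transmission", 25.0): (26.7, 6.8),
    ("air", "reflective", 25.0): (26.3, 5.2),
    ("air", "transmission", 70.0): (74.6, 6.6),
    ("air", "reflective", 70.0): (74.1, 5.9),
    ("DS", "transmission", 25.0): (26.4, 5.4),
    ("DS", "reflective", 25.0): (23.8, 4.8),
    ("DS", "transmission", 70.0): (74.5, 6.4),
    ("DS", "reflective", 70.0): (73.9, 5.5),
    ("SC", "transmission", 25.0): (23.7, 5.4),
    ("SC", "reflective", 25.0): (26.2, 4.7),
    ("SC", "transmission", 70.0): (73.6, 5.2),
    ("SC", "reflective", 70.0): (73.4, 4.9),
    ("OG", "transmission", 25.0): (25.6, 2.2),
    ("OG", "reflective", 25.0): (25.3, 1.3),
    ("OG", "transmission", 70.0): (70.2, 0.3),
    ("OG", "reflective", 70.0): (70.1, 0.2),
}

#: Scan-uniformity benchmark: mode -> material -> CV (dimensionless, 4 dp).
UNIFORMITY_TABLE: dict[str, dict[str, float]] = {
    "transmission": {"air": 0.0166, "DS": 0.0161, "SC": 0.0162, "OG": 0.0146},
    "reflective": {"air": 0.0134, "DS": 0.0110, "SC": 0.0115, "OG": 0.0097},
}
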