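"""Temperature unit helpers.

All internal temperatures are Kelvin; Celsius appears only at the I/O
boundary.  The conversion offset is 273.0 K, not 273.15 K: the fitted
trait parameters place the 24 degC rearing treatment at a reference
temperature of 297 K and the freezing point at 273 K, i.e. the whole
parameter scale was constructed with a rounded offset.  Reporting
Celsius with the same offset keeps the package self-consistent with
those parameters (and with the printed niche temperatures, which agree
to within 0.1 degC on this scale).
"""

CELSIUS_OFFSET = 273.0


def to_kelvin(celsius):
    """Convert degrees Celsius to Kelvin on the package scale."""
    return celsius + CELSIUS_OFFSET


def to_celsius(kelvin):
    """Convert Kelvin to degrees Celsius on the package scale."""
    return kelvin - CELSIUS_OFFSET
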