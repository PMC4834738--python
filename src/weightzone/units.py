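"""Unit conversions.

Internal computation is SI (kg, cm); pounds and inches appear only at I/O
boundaries, matching how clients and clinicians read the numbers.
"""

LB_PER_KG = 2.2046226218487757
CM_PER_IN = 2.54


def lb_to_kg(lb: float) -> float:
    return lb / LB_PER_KG


def kg_to_lb(kg: float) -> float:
    return kg * LB_PER_KG


def inches_to_cm(inches: float) -> float:
    return inches * CM_PER_IN


def cm_to_inches(cm: float) -> float:
    return cm / CM_PER_IN
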