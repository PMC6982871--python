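"""Bundled reference catalogs for the single-inhabitant smart-lab deployment.

These constants describe the default experimental setup the package ships
with: the 30 binary sensors installed in the lab, the 24 raw activity
classes with their recorded instance counts and time-routine tags, and the
class-merge map used when restructuring the raw catalog into the final
12-class one.  All of them can be replaced by user-supplied CSV/YAML files;
they are plain data, not behaviour.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Sensor registry: (sensor_id, object label, sensor type, (state_a, state_b)).
# The first state of each pair is the "active" one (triggered / occupied).
# ---------------------------------------------------------------------------

SENSOR_TABLE: list[tuple[str, str, str, tuple[str, str]]] = [
    ("SM1", "Kitchen area", "Motion", ("Movement", "No movement")),
    ("SM3", "Bathroom area", "Motion", ("Movement", "No movement")),
    ("SM4", "Bedroom area", "Motion", ("Movement", "No movement")),
    ("SM5", "Sofa area", "Motion", ("Movement", "No movement")),
    ("M01", "Door", "Contact", ("Open", "Close")),
    ("TV0", "TV", "Contact", ("Open", "Close")),
    ("D01", "Refrigerator", "Contact", ("Open", "Close")),
    ("D02", "Microwave", "Contact", ("Open", "Close")),
    ("D03", "Wardrobe", "Contact", ("Open", "Close")),
    ("D04", "Cups cupboard", "Contact", ("Open", "Close")),
    ("D05", "Dishwasher", "Contact", ("Open", "Close")),
    ("D07", "WC", "Contact", ("Open", "Close")),
    ("D08", "Closet", "Contact", ("Open", "Close")),
    ("D09", "Washing machine", "Contact", ("Open", "Close")),
    ("D10", "Pantry", "Contact", ("Open", "Close")),
    ("C01", "Medication box", "Contact", ("Open", "Close")),
    ("C02", "Fruit platter", "Contact", ("Open", "Close")),
    ("C03", "Cutlery", "Contact", ("Open", "Close")),
    ("C04", "Pots", "Contact", ("Open", "Close")),
    ("C05", "Water bottle", "Contact", ("Open", "Close")),
    ("C07", "XBOX Remote", "Contact", ("Present", "Not present")),
    ("C08", "Trash", "Contact", ("Open", "Close")),
    ("C09", "Tap", "Contact", ("Open", "Close")),
    ("C10", "Tank", "Contact", ("Open", "Close")),
    ("C12", "Laundry basket", "Contact", ("Present", "Not present")),
    ("C13", "Pyjamas drawer", "Contact", ("Open", "Close")),
    ("C14", "Bed", "Pressure", ("Pressure", "No pressure")),
    ("C15", "Kitchen faucet", "Contact", ("Open", "Close")),
    ("H01", "Kettle", "Contact", ("Open", "Close")),
    ("S09", "Sofa", "Pressure", ("Pressure", "No pressure")),
]

SENSOR_TYPES = ("Motion", "Contact", "Pressure")

# ---------------------------------------------------------------------------
# Raw activity catalog: class id -> (name, instance count, routine tags).
# Routine tags: M = Morning, A = Afternoon, E = Evening.
# ---------------------------------------------------------------------------

RAW_ACTIVITIES: dict[str, tuple[str, int, tuple[str, ...]]] = {
    "Act01": ("Take Medication", 52, ("A", "E")),
    "Act02": ("Prepare Breakfast", 63, ("M",)),
    "Act03": ("Prepare lunch", 118, ("A",)),
    "Act04": ("Prepare Dinner", 76, ("E",)),
    "Act05": ("Breakfast", 78, ("M",)),
    "Act06": ("Lunch", 101, ("A",)),
    "Act07": ("Dinner", 86, ("E",)),
    "Act08": ("Eat a snack", 12, ("A",)),
    "Act09": ("Watch TV", 70, ("A", "E")),
    "Act10": ("Enter Smart Lab", 21, ("A", "E")),
    "Act11": ("Play a videogame", 28, ("M", "E")),
    "Act12": ("Relax on the sofa", 85, ("M", "A", "E")),
    "Act13": ("Leave Smart Lab", 33, ("M", "A")),
    "Act14": ("Visitor to Smart Lab", 7, ("M", "A")),
    "Act15": ("Put waste in the bin", 75, ("A", "E")),
    "Act16": ("Wash hands", 22, ("M",)),
    "Act17": ("Brush teeth", 132, ("M", "A", "E")),
    "Act18": ("Use the toilet", 44, ("M", "A", "E")),
    "Act19": ("Wash dishes", 13, ("A", "E")),
    "Act20": ("Put washing in machine", 20, ("M", "A")),
    "Act21": ("Work at the table", 20, ("M",)),
    "Act22": ("Dressing", 86, ("M", "A", "E")),
    "Act23": ("Go to bed", 30, ("E",)),
    "Act24": ("Wake up", 32, ("M",)),
}

RAW_CLASS_COUNTS: dict[str, int] = {k: v[1] for k, v in RAW_ACTIVITIES.items()}

# ---------------------------------------------------------------------------
# Restructuring plan: merge similar classes, then drop classes with fewer
# than MIN_INSTANCES instances.
# ---------------------------------------------------------------------------

MERGE_MAP: dict[str, list[str]] = {
    "ActN1": ["Act10", "Act13", "Act14"],   # single door sensor
    "ActN2": ["Act09", "Act12"],            # sitting on the sofa
    "ActN3": ["Act02", "Act05"],            # breakfast
    "ActN4": ["Act03", "Act06"],            # lunch
    "ActN5": ["Act04", "Act07"],            # dinner
}

MIN_INSTANCES = 30

#: Routine tags of the restructured 12-class catalog (merged classes take
#: the union of their sources' routines).
RESTRUCTURED_ROUTINES: dict[str, tuple[str, ...]] = {
    "Act01": ("A", "E"),
    "Act15": ("A", "E"),
    "Act17": ("M", "A", "E"),
    "Act18": ("M", "A", "E"),
    "Act22": ("M", "A", "E"),
    "Act23": ("E",),
    "Act24": ("M",),
    "ActN1": ("M", "A", "E"),
    "ActN2": ("M", "A", "E"),
    "ActN3": ("M",),
    "ActN4": ("A",),
    "ActN5": ("E",),
}

#: Activity groups whose members fire near-identical sensor sets.  Used by
#: the simulator to emulate interclass similarity.
SIMILARITY_GROUPS: dict[str, tuple[str, ...]] = {
    "M01": ("ActN1",),
    "C14": ("Act23", "Act24"),
    "S09": ("ActN2",),
    "SM1": ("ActN3", "ActN4", "ActN5"),
}
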