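"""Homologous feature schema shared by the human and macaque cohorts.

Every subject, regardless of species, is described by the same 260 named
structural features: 92 regional gray-matter volumes (46 bilateral region
pairs of a regional-map-style cortical/subcortical parcellation) and 42
white-matter tracts (a cross-species tract atlas) measured with four
diffusion metrics (FA, MD, AD, RD), 92 + 4 x 42 = 260.  Homology of the
parcellation is what makes a model trained in one species applicable to
the other, so the schema is validated strictly: a feature table either
matches it exactly or the error names every offending column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MEASURES = ("GMV", "FA", "MD", "AD", "RD")
DIFFUSION_MEASURES = ("FA", "MD", "AD", "RD")
HEMISPHERES = ("L", "R", "midline")

#: hemisphere token used inside feature names
_HEMI_TOKEN = {"L": "left", "R": "right", "midline": "mid"}

# Regional-map-style cortical/subcortical labels (bilateral pairs).  The
# first 40 are anatomical labels of the kind used with this parcellation
# (prefrontal/premotor/cingulate/parietal/temporal/visual sectors plus
# subcortical nuclei); the remainder are synthetic placeholder labels that
# pad the list to the 46 pairs the 92-region parcellation requires.  Users
# with a concrete atlas can supply their own label list.
GM_LABELS = (
    "PFCdl", "PFCvl", "PFCcl", "PFCdm", "PFCm", "PFCol", "PFCom", "PFCpol",
    "PMCdl", "PMCm", "PMCvl", "M1", "FEF",
    "CCa", "CCp", "CCr", "CCs",
    "PCs", "PCi", "PCip", "PCm",
    "Ia", "Ip", "S1", "S2",
    "TCc", "TCi", "TCpol", "TCs", "TCv",
    "A1", "A2", "V1", "V2", "VACd", "VACv",
    "HC", "PHC", "Amyg", "Cd", "Pu", "GP", "Tha",
    # synthetic padding labels (no anatomical referent)
    "SYN44", "SYN45", "SYN46",
)

# Cross-species white-matter tract labels: 19 bilateral pairs plus 4
# commissural/midline tracts = 42 tract features per diffusion measure.
WM_BILATERAL_LABELS = (
    "AF", "SLF1", "SLF2", "SLF3", "IFOF", "UF", "CT", "STR", "OR",
    "Cs:Pg", "ILF", "MDLF", "ATR", "FX", "CBD", "CBP", "CBT", "VOF", "FAT",
)
WM_MIDLINE_LABELS = ("AC", "FM", "FMI", "MCP")

N_GM_FEATURES = 92
N_TRACTS = 42
N_FEATURES = N_GM_FEATURES + len(DIFFUSION_MEASURES) * N_TRACTS  # 260


class SchemaError(ValueError):
    """A table does not match the feature schema; message lists columns."""


def feature_name(measure: str, hemisphere: str, label: str) -> str:
    """Canonical feature name ``<MEASURE>_<left|right|mid>_<label>``."""
    return f"{measure}_{_HEMI_TOKEN[hemisphere]}_{label}"


@dataclass(frozen=True)
class FeatureSchema:
    """The 260-feature homologous schema as an ordered metadata table.

    ``table`` has one row per feature with columns feature_name, measure,
    compartment, structure_label, hemisphere, in canonical column order.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"feature_name", "measure", "compartment",
                    "structure_label", "hemisphere"}
        if not required.issubset(t.columns):
            raise SchemaError(f"schema table missing columns "
                              f"{sorted(required - set(t.columns))}")
        if t["feature_name"].duplicated().any():
            dups = t.loc[t["feature_name"].duplicated(), "feature_name"]
            raise SchemaError(f"duplicate feature names: {sorted(set(dups))}")
        counts = t["measure"].value_counts()
        if counts.get("GMV", 0) != N_GM_FEATURES:
            raise SchemaError(
                f"expected {N_GM_FEATURES} GMV features, got {counts.get('GMV', 0)}")
        for m in DIFFUSION_MEASURES:
            if counts.get(m, 0) != N_TRACTS:
                raise SchemaError(
                    f"expected {N_TRACTS} {m} features, got {counts.get(m, 0)}")
        gm_ok = (t.loc[t["measure"] == "GMV", "compartment"] == "gray_matter").all()
        wm_ok = (t.loc[t["measure"] != "GMV", "compartment"] == "white_matter").all()
        if not (gm_ok and wm_ok):
            raise SchemaError("measure/compartment mismatch: GMV must be "
                              "gray_matter, diffusion measures white_matter")

    @property
    def feature_names(self) -> list[str]:
        return list(self.table["feature_name"])

    @property
    def n_features(self) -> int:
        return len(self.table)

    def names_for_measure(self, measure: str) -> list[str]:
        return list(self.table.loc[self.table["measure"] == measure,
                                   "feature_name"])

    def names_for_compartment(self, compartment: str) -> list[str]:
        return list(self.table.loc[self.table["compartment"] == compartment,
                                   "feature_name"])

    def measure_of(self, name: str) -> str:
        row = self.table.loc[self.table["feature_name"] == name]
        if row.empty:
            raise KeyError(name)
        return str(row["measure"].iloc[0])

    def validate_columns(self, columns) -> None:
        """Raise :class:`SchemaError` naming every missing/extra column."""
        expected = set(self.feature_names)
        got = set(columns)
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing feature columns: {missing}")
            if extra:
                parts.append(f"unexpected feature columns: {extra}")
            raise SchemaError("; ".join(parts))


def build_default_schema(gm_labels=GM_LABELS,
                         wm_bilateral=WM_BILATERAL_LABELS,
                         wm_midline=WM_MIDLINE_LABELS) -> FeatureSchema:
    """Construct the default 260-feature schema.

    92 GMV features (46 bilateral gray-matter label pairs), and for each of
    FA/MD/AD/RD the same 42 tract features (19 bilateral pairs + 4 midline
    tracts).  Custom label lists may be supplied as long as they produce
    46 gray-matter pairs and 42 tract slots.
    """
    rows = []
    for label in gm_labels:
        for hemi in ("L", "R"):
            rows.append((feature_name("GMV", hemi, label), "GMV",
                         "gray_matter", label, hemi))
    for measure in DIFFUSION_MEASURES:
        for label in wm_bilateral:
            for hemi in ("L", "R"):
                rows.append((feature_name(measure, hemi, label), measure,
                             "white_matter", label, hemi))
        for label in wm_midline:
            rows.append((feature_name(measure, "midline", label), measure,
                         "white_matter", label, "midline"))
    table = pd.DataFrame(rows, columns=["feature_name", "measure",
                                        "compartment", "structure_label",
                                        "hemisphere"])
    return FeatureSchema(table)
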