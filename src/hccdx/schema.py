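"""Declarative dataset schemas for clinical tables.

A :class:`DatasetSchema` records, per feature, its measurement scale
(dichotomous / ordinal / ratio), admissible range, marginal mean and SD,
and missingness rate. :func:`builtin_hcc_schema` ships the CHUC HCC
survival table layout (165 patients, 49 features, binary one-year survival
label) so the rest of the toolkit can be exercised without the original
data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

KINDS = ("dichotomous", "ordinal", "ratio")

#: qualitative scales take integer codes; ratio features are continuous
QUALITATIVE_KINDS = ("dichotomous", "ordinal")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's scale, range, marginal moments and missingness rate."""

    name: str
    kind: str
    low: float
    high: float
    mean: float
    sd: float
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if not (self.low <= self.mean <= self.high):
            raise ValueError(f"{self.name}: mean {self.mean} outside [{self.low}, {self.high}]")
        if self.sd < 0:
            raise ValueError(f"{self.name}: negative sd {self.sd}")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError(f"{self.name}: missing_rate {self.missing_rate} not in [0,1]")
        if self.kind == "dichotomous" and (self.low, self.high) != (0.0, 1.0):
            raise ValueError(f"{self.name}: dichotomous features must have range [0,1]")

    @property
    def qualitative(self) -> bool:
        return self.kind in QUALITATIVE_KINDS


@dataclass
class DatasetSchema:
    """Ordered feature specs plus the label column's identity."""

    features: list[FeatureSpec]
    label_name: str = "Class"
    positive_label_meaning: str = "lives"

    def __post_init__(self):
        if not self.features:
            raise ValueError("schema needs at least one feature")
        names = [normalize_name(f.name) for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def kind_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in KINDS}
        for f in self.features:
            counts[f.kind] += 1
        return counts

    def n_qualitative(self) -> int:
        return sum(1 for f in self.features if f.qualitative)

    def n_quantitative(self) -> int:
        return len(self.features) - self.n_qualitative()


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed feature-name key."""
    return " ".join(name.strip().lower().split())


def save_schema(schema: DatasetSchema, path) -> None:
    doc = {
        "label_name": schema.label_name,
        "positive_label_meaning": schema.positive_label_meaning,
        "features": [asdict(f) for f in schema.features],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_schema(path) -> DatasetSchema:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    feats = [FeatureSpec(**d) for d in doc["features"]]
    return DatasetSchema(
        features=feats,
        label_name=doc.get("label_name", "Class"),
        positive_label_meaning=doc.get("positive_label_meaning", "lives"),
    )


# CHUC HCC survival table: (name, kind, low, high, mean, sd, missing %).
# Ranges, moments and missingness are reproduced verbatim from the published
# summary table, including its implausible units (e.g. Leukocytes 2.2-13000,
# Platelets 1.71-459000); the schema does not second-guess the source.
_HCC_ROWS = [
    ("Gender", "dichotomous", 0, 1, 0.806, 0.397, 0.0),
    ("Symptoms", "dichotomous", 0, 1, 0.639, 0.482, 10.91),
    ("Alcohol", "dichotomous", 0, 1, 0.739, 0.440, 0.0),
    ("Hepatitis B Surface Antigen", "dichotomous", 0, 1, 0.108, 0.312, 10.3),
    ("Hepatitis B E Antigen", "dichotomous", 0, 1, 0.008, 0.089, 23.64),
    ("Hepatitis B Core Antibody", "dichotomous", 0, 1, 0.270, 0.445, 14.55),
    ("Hepatitis C Virus Antibody", "dichotomous", 0, 1, 0.218, 0.414, 5.45),
    ("Cirrhosis", "dichotomous", 0, 1, 0.903, 0.297, 0.0),
    ("Endemic Countries", "dichotomous", 0, 1, 0.079, 0.271, 23.64),
    ("Smoking", "dichotomous", 0, 1, 0.508, 0.502, 24.85),
    ("Diabetes", "dichotomous", 0, 1, 0.346, 0.477, 1.82),
    ("Obesity", "dichotomous", 0, 1, 0.129, 0.336, 6.06),
    ("Hemochromatosis", "dichotomous", 0, 1, 0.049, 0.217, 13.94),
    ("Arterial Hypertension", "dichotomous", 0, 1, 0.364, 0.483, 1.82),
    ("Chronic Renal Insufficiency", "dichotomous", 0, 1, 0.123, 0.329, 1.21),
    ("Human Immunodeficiency Virus", "dichotomous", 0, 1, 0.020, 0.140, 8.48),
    ("Nonalcoholic Steatohepatitis", "dichotomous", 0, 1, 0.056, 0.231, 13.33),
    ("Esophageal Varices", "dichotomous", 0, 1, 0.611, 0.490, 31.52),
    ("Splenomegaly", "dichotomous", 0, 1, 0.560, 0.498, 9.09),
    ("Portal Hypertension", "dichotomous", 0, 1, 0.714, 0.453, 6.67),
    ("Portal Vein Thrombosis", "dichotomous", 0, 1, 0.222, 0.417, 1.82),
    ("Liver Metastasis", "dichotomous", 0, 1, 0.224, 0.418, 2.42),
    ("Radiological Hallmark", "dichotomous", 0, 1, 0.681, 0.468, 1.21),
    ("Age at diagnosis", "ratio", 20, 93, 64.691, 13.32, 0.0),
    ("Grams of Alcohol per day", "ratio", 0, 500, 71.009, 76.278, 29.09),
    ("Packs of cigarettes per year", "ratio", 0, 510, 20.464, 51.565, 32.12),
    ("Performance status", "ordinal", 0, 4, 1.018, 1.182, 0.0),
    ("Encephalopathy degree", "ordinal", 1, 3, 1.159, 0.428, 0.61),
    ("Ascites degree", "ordinal", 1, 3, 1.442, 0.686, 1.21),
    ("International Normalized Ratio (INR)", "ratio", 0.84, 4.82, 1.422, 0.478, 2.42),
    ("Alpha-FetoProtein (ng/mL)", "ratio", 1.2, 1810346, 19299.95, 149098.34, 4.85),
    ("Hemoglobin (g/dL)", "ratio", 5, 18.7, 12.879, 2.145, 1.82),
    ("Mean Corpuscular Volume (fl)", "ratio", 69.5, 119.6, 95.120, 8.406, 1.82),
    ("Leukocytes (G/L)", "ratio", 2.2, 13000, 1473.962, 2909.11, 1.82),
    ("Platelets (G/L)", "ratio", 1.71, 459000, 113206.44, 107118.63, 1.82),
    ("Albumin (mg/dL)", "ratio", 1.9, 4.9, 3.446, 0.685, 3.64),
    ("Total Bilirubin (mg/dL)", "ratio", 0.3, 40.5, 3.088, 5.499, 3.03),
    ("Alanine transaminase (U/L)", "ratio", 11, 420, 67.093, 57.540, 2.42),
    ("Aspartate transaminase (U/L)", "ratio", 17, 553, 96.383, 87.484, 1.82),
    ("Gamma-glutamyl transferase (U/L)", "ratio", 23, 1575, 268.027, 258.750, 1.82),
    ("Alkaline phosphatase (U/L)", "ratio", 1.28, 980, 212.212, 167.944, 1.82),
    ("Total Proteins (g/dL)", "ratio", 3.9, 102, 8.961, 11.726, 6.67),
    ("Creatinine (mg/dL)", "ratio", 0.2, 7.6, 1.127, 0.956, 4.24),
    ("Number of Nodules", "ratio", 0, 5, 2.736, 1.798, 1.21),
    ("Major dimension of nodule (cm)", "ratio", 1.5, 22, 6.851, 5.095, 12.12),
    ("Direct Bilirubin (mg/dL)", "ratio", 0.1, 29.3, 1.930, 4.210, 26.67),
    ("Iron (mcg/dL)", "ratio", 0, 224, 85.599, 55.699, 47.88),
    ("Oxygen Saturation (%)", "ratio", 0, 126, 37.029, 28.994, 48.48),
    ("Ferritin (ng/mL)", "ratio", 0, 2230, 438.998, 457.114, 48.48),
]


def builtin_hcc_schema() -> DatasetSchema:
    """The CHUC HCC survival schema: 49 features, label 0 = dies, 1 = lives.

    26 features are qualitative (23 dichotomous risk factors / findings plus
    3 ordinal severity grades) and 23 are quantitative laboratory or
    demographic measurements. Missingness rates are percentages converted to
    fractions; they average about 10.22% over the table.
    """
    feats = [
        FeatureSpec(name=n, kind=k, low=float(lo), high=float(hi),
                    mean=float(mu), sd=float(sd), missing_rate=float(miss) / 100.0)
        for (n, k, lo, hi, mu, sd, miss) in _HCC_ROWS
    ]
    return DatasetSchema(features=feats, label_name="Class",
                         positive_label_meaning="lives")
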