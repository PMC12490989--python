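"""The fixed 13-node cohort schema.

The analysis operates on a fixed variable set spanning three dimensions:

* **physical** (7 nodes): body-mass index, hypertension flag, fasting
  glucose, fasting insulin, total cholesterol, triacylglycerol, HOMA-IR;
* **psychological** (3 nodes): depression, anxiety and stress scores;
* **nutritional** (3 nodes): empirical nutritional-pattern factor scores
  (NP1 minerals/vitamins, NP2 carbohydrates, NP3 fat/sodium).

Hypertension is the only binary node; everything else is continuous.
Published tables spell several variables in more than one way, so a
case-insensitive alias map translates incoming column headers to the
canonical short identifiers used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError

#: Canonical node identifiers, in schema order.
NODES: tuple[str, ...] = (
    "BMI",
    "HTN",
    "Glucose",
    "Insulin",
    "CholesT",
    "TAG",
    "HOMA",
    "Depre",
    "Anxiety",
    "Stress",
    "NP1",
    "NP2",
    "NP3",
)

#: Dimension label per node.
DIMENSIONS: dict[str, str] = {
    "BMI": "physical",
    "HTN": "physical",
    "Glucose": "physical",
    "Insulin": "physical",
    "CholesT": "physical",
    "TAG": "physical",
    "HOMA": "physical",
    "Depre": "psychological",
    "Anxiety": "psychological",
    "Stress": "psychological",
    "NP1": "nutritional",
    "NP2": "nutritional",
    "NP3": "nutritional",
}

#: Variable kind per node; HTN is the single dichotomous variable.
KINDS: dict[str, str] = {node: "continuous" for node in NODES}
KINDS["HTN"] = "binary"

#: Optional demographic columns carried through I/O untouched.
DEMOGRAPHIC_COLUMNS: tuple[str, ...] = ("subject_id", "sex", "marital", "ses", "age")

# Lower-cased header -> canonical node ID.  Covers the long labels, the
# figure/table short IDs and common programmatic spellings.
_ALIASES: dict[str, str] = {
    "bmi": "BMI",
    "body mass index": "BMI",
    "body_mass_index": "BMI",
    "htn": "HTN",
    "hypertension": "HTN",
    "glucose": "Glucose",
    "fasting glucose": "Glucose",
    "insulin": "Insulin",
    "fasting insulin": "Insulin",
    "cholest": "CholesT",
    "cholesterol-t": "CholesT",
    "cholesterol_t": "CholesT",
    "cholesterol-total": "CholesT",
    "cholesterol total": "CholesT",
    "total cholesterol": "CholesT",
    "tag": "TAG",
    "triacylglycerol": "TAG",
    "triglycerides": "TAG",
    "homa": "HOMA",
    "homa-ir": "HOMA",
    "homa_ir": "HOMA",
    "homa-ir index": "HOMA",
    "homa ir": "HOMA",
    "depre": "Depre",
    "depression": "Depre",
    "anxiety": "Anxiety",
    "stress": "Stress",
    "np1": "NP1",
    "np2": "NP2",
    "np3": "NP3",
    "nutritional pattern 1": "NP1",
    "nutritional pattern 2": "NP2",
    "nutritional pattern 3": "NP3",
}


def canonical_node(name: str) -> str | None:
    """Map a column header to its canonical node ID, or None if it is not
    one of the 13 node variables."""
    return _ALIASES.get(str(name).strip().lower())


@dataclass(frozen=True)
class NodeSchema:
    """The ordered 13-node variable set with dimension and kind labels."""

    nodes: tuple[str, ...] = NODES
    dimension: dict[str, str] = field(default_factory=lambda: dict(DIMENSIONS))
    kind: dict[str, str] = field(default_factory=lambda: dict(KINDS))

    def __post_init__(self) -> None:
        if len(self.nodes) != 13 or len(set(self.nodes)) != 13:
            raise SchemaError("schema requires exactly 13 unique node identifiers")
        counts = {"physical": 0, "psychological": 0, "nutritional": 0}
        for node in self.nodes:
            dim = self.dimension.get(node)
            if dim not in counts:
                raise SchemaError(f"node {node!r} has unknown dimension {dim!r}")
            counts[dim] += 1
        if (counts["physical"], counts["psychological"], counts["nutritional"]) != (7, 3, 3):
            raise SchemaError(
                "dimension assignment must be 7 physical / 3 psychological / 3 nutritional, "
                f"got {counts}"
            )
        binary = [n for n in self.nodes if self.kind.get(n) == "binary"]
        if binary != ["HTN"]:
            raise SchemaError(f"HTN must be the only binary node, got {binary}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_potential_edges(self) -> int:
        """Number of unordered node pairs, n(n-1)/2."""
        n = len(self.nodes)
        return n * (n - 1) // 2

    def index(self, node: str) -> int:
        return self.nodes.index(node)


#: Shared default schema instance.
DEFAULT_SCHEMA = NodeSchema()
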