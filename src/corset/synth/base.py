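"""Ground-truth bookkeeping for the synthetic-data generators.

Every generator returns its artifact together with a :class:`GroundTruth`
record holding the generator name, every numeric parameter and the seed, so
any downstream recovery test can compare against the exact simulated truth
and any artifact can be regenerated bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field


@dataclass
class GroundTruth:
    kind: str
    params: dict
    seed: int | None
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"kind": self.kind, "params": self.params, "seed": self.seed,
                 "warnings": self.warnings},
                fh,
                indent=2,
                default=_jsonify,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], params=d["params"], seed=d["seed"],
                   warnings=d.get("warnings", []))


def _jsonify(obj):
    try:
        return obj.tolist()
    except AttributeError:
        return float(obj)
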