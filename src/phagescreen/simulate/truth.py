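"""Ground-truth sidecar for simulated datasets."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["SimTruth"]


@dataclass
class SimTruth:
    """What a simulation actually put into the data.

    Attributes
    ----------
    depletion_effect
        member id -> true log2 survival effect under infection
        (0 = neutral, negative = depleted).
    abundance
        member id -> baseline proportion; must sum to 1.
    spiked_interactors
        ``(host, bait)`` -> set of protein ids spiked as interactors.
    adsorption_factor
        ``k > 0`` in the survival model ``exp(-MOI_e / k)``.
    seed
        Seed the generator was called with.
    """

    depletion_effect: dict[str, float] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)
    spiked_interactors: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    adsorption_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance:
            total = sum(self.abundance.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(f"abundances sum to {total}, not 1")
        if self.adsorption_factor <= 0:
            raise ValueError("adsorption_factor must be > 0")
        for eff in self.depletion_effect.values():
            if not math.isfinite(eff):
                raise ValueError("effects must be finite")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["spiked_interactors"] = {
            f"{h}\t{ag}": sorted(v) for (h, ag), v in self.spiked_interactors.items()
        }
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        spiked = {
            tuple(k.split("\t")): set(v)
            for k, v in d.get("spiked_interactors", {}).items()
        }
        return cls(
            depletion_effect=d.get("depletion_effect", {}),
            abundance=d.get("abundance", {}),
            spiked_interactors=spiked,  # type: ignore[arg-type]
            adsorption_factor=d.get("adsorption_factor", 1.0),
            seed=d.get("seed", 0),
        )
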