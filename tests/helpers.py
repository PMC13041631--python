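"""Tiny shared test utilities (imported by conftest and test modules)."""

from __future__ import annotations

from divnav import GenerationStep, make_record


def make_step(smiles, step: int = 0, scores=None) -> GenerationStep:
    """Build a GenerationStep from raw SMILES strings (invalid ones kept)."""
    if scores is None:
        scores = [None] * len(smiles)
    return GenerationStep(
        step=step,
        records=[make_record(step, s, score=sc) for s, sc in zip(smiles, scores)],
    )
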