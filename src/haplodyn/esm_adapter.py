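"""Optional adapter exposing the ESM-1v protein language models as position
scorers.

The adapter is isolated on purpose: the core package never imports it, and it
activates only when the ``fair-esm`` package (and its torch dependency) is
installed and model weights are available locally or downloadable.  Each of
the ensemble members ``esm1v_t33_650M_UR90S_1..5`` becomes one
:class:`~haplodyn.fitness.PositionScorer`; PLLR scoring then proceeds through
the ordinary :func:`haplodyn.fitness.pllr` path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EsmScorer", "load_esm_ensemble"]


class EsmScorer:
    """Position scorer backed by one ESM-1v model (single unmasked forward
    pass; log-softmax over the amino-acid vocabulary at each position)."""

    def __init__(self, model, alphabet, identifier: str):
        self.model = model
        self.alphabet = alphabet
        self.identifier = identifier
        self._converter = alphabet.get_batch_converter()

    def score(self, sequence: str) -> np.ndarray:
        import torch

        _, _, tokens = self._converter([(self.identifier, sequence)])
        with torch.no_grad():
            logits = self.model(tokens)["logits"][0]
        logp = torch.log_softmax(logits, dim=-1)
        idx = [self.alphabet.get_idx(a) for a in sequence]
        # token 0 is BOS; position i of the sequence is token i+1
        out = logp[np.arange(1, len(sequence) + 1), idx]
        return out.cpu().numpy()


def load_esm_ensemble(members: tuple[int, ...] = (1, 2, 3)) -> list[EsmScorer]:
    """Load ESM-1v ensemble members (default: models 1-3).

    Raises ``ImportError`` with guidance when fair-esm is not installed.
    """
    try:
        import esm
    except ImportError as err:  # pragma: no cover - exercised only with fair-esm
        raise ImportError(
            "the ESM adapter requires the optional 'fair-esm' package "
            "(pip install fair-esm) and local model weights"
        ) from err
    scorers = []
    for k in members:  # pragma: no cover - requires external weights
        name = f"esm1v_t33_650M_UR90S_{k}"
        model, alphabet = getattr(esm.pretrained, name)()
        model.eval()
        scorers.append(EsmScorer(model, alphabet, identifier=name))
    return scorers
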