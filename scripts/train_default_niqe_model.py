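"""Regenerate the bundled NIQE model from seeded synthetic natural textures.

The bundled model (src/climbfocus/data/niqe_model_synthetic.json) is trained
by the package's own trainer on power-law-spectrum textures; it is synthetic
by construction and can be regenerated deterministically with this script.
Users imaging real specimens should retrain on their own pristine micrographs
(`climbfocus niqe train <dir>`).
"""

from pathlib import Path

from climbfocus.niqe import train_model
from climbfocus.simulate import natural_texture

N_IMAGES = 16
SHAPE = (384, 384)
SEED0 = 1000

def main() -> None:
    corpus = [natural_texture(SHAPE, seed=SEED0 + i) for i in range(N_IMAGES)]
    model = train_model(corpus)
    out = Path(__file__).resolve().parents[1] / "src/climbfocus/data/niqe_model_synthetic.json"
    model.to_json(out)
    print(f"wrote {out} ({out.stat().st_size} bytes, "
          f"{model.mean_vec.size}-dim features)")


if __name__ == "__main__":
    main()
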