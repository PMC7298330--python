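"""Generate a parallel item set and render stimulus sheets.

Builds three isomorph items per visual-load level (the 3 x 3 layout of a
pilot study), writes the level-3 item's learning and answer sheets as PNGs,
and prints the structural summary of one item.
"""

from collections import Counter
from pathlib import Path

from figmem import (
    RenderConfig,
    generate_parallel_set,
    render_answer_sheet,
    render_learning_sheet,
    scoring_manifest,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

for level in (1, 2, 3):
    items = generate_parallel_set(level, n_items=3, master_seed=2024)
    print(f"visual-load level {level}: {len(items)} isomorph items, "
          f"seeds {[it.incidental_seed for it in items]}")

item = items[0]  # a level-3 item
cfg = RenderConfig(cell_px=96)
render_learning_sheet(item, cfg).save(out / "learning_sheet.png")
render_answer_sheet(item, cfg, "vertical").save(out / "answer_sheet.png")

balance = Counter(d.key for u in item.units for d in u.distractors)
print(f"\nitem with seed {item.incidental_seed}: {item.n_units} emblem-frame units")
print(f"each of the 20 frames appears {set(balance.values())} times as a distractor")
key = scoring_manifest(item, "vertical")["correct_option_by_recall_position"]
print(f"scoring key (first recall positions): "
      f"{dict(list(key.items())[:5])}")
print("-> the key maps each recall position to the answer slot (0-3) that")
print("   holds the frame the emblem was learned with; wrote 2 PNG sheets.")
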