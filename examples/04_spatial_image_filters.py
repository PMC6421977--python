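"""Turn an annotated section image into a clickable spatial filter.

Generates a synthetic stained-section stand-in with one annotated blob per
hippocampal subfield, registers it with tags and a patient association,
then clicks inside regions: each click toggles that region's value in a
spatial filter card, and the active row set follows.
"""

import tempfile

from cardlink import Board, ImageRegistry, generate_clinical_dataset, hit_test, load_annotation
from cardlink.fixtures import FixtureConfig, generate_section_image

cfg = FixtureConfig(seed=4)
ds = generate_clinical_dataset(cfg)
board = Board(ds)
registry = ImageRegistry(board)

with tempfile.TemporaryDirectory() as tmp:
    img_path, ann_path = generate_section_image(cfg, patient="Az1", size=256, out_dir=tmp)
    card = registry.register_image(img_path, tags={"NeuN"}, associations={"Patient": "Az1"})
    registry.attach_spatial(card, load_annotation(ann_path))

print(f"registered {card.image_id}: {card.width}x{card.height}, tags={card.tags}, "
      f"associations={card.associations}")
print(f"retrievable by tag: {len(registry.query_images(tag='NeuN'))} card(s)")

centroids = {r.value: r.shape().centroid.coords[0] for r in card.spatial.regions}
print(f"\nhit test at CA1 centroid -> {hit_test(card.spatial, centroids['CA1'])!r}")

registry.click_to_filter(card, centroids["CA1"])
print(f"click CA1:      {len(board.active_rows)} active rows (only CA1)")
registry.click_to_filter(card, centroids["DG"])
print(f"click DG too:   {len(board.active_rows)} active rows (CA1 or DG)")
registry.click_to_filter(card, centroids["CA1"])
registry.click_to_filter(card, centroids["DG"])
print(f"toggle both off: {len(board.active_rows)} active rows (back to pass-all)")
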