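"""NIfTI-1 persistence for phantom cases.

Stations keep their preprocessed images in per-site ``train/`` and
``validation/`` folders as NIfTI pairs — ``<patient>_img.nii.gz``
(float32) and ``<patient>_msk.nii.gz`` (uint8 {0,1}) with an identity
affine.  The round trip through this module is bit-lossless, which the
data-loading tests assert.
"""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, DataError, FormatError
from .phantoms import PartitionedCohort, PhantomCase

_IMG_SUFFIX = "_img.nii.gz"
_MSK_SUFFIX = "_msk.nii.gz"


def case_filenames(patient_id: str) -> tuple[str, str]:
    return patient_id + _IMG_SUFFIX, patient_id + _MSK_SUFFIX


def write_case_nifti(
    case: PhantomCase, directory, force: bool = False
) -> tuple[Path, Path]:
    """Write one image/mask NIfTI pair; refuses to overwrite unless ``force``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    case.validate()
    img_name, msk_name = case_filenames(case.patient_id)
    img_path = directory / img_name
    msk_path = directory / msk_name
    if not force:
        for p in (img_path, msk_path):
            if p.exists():
                raise ConfigurationError(
                    f"refusing to overwrite existing file {p} (pass force=True)"
                )
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(case.image.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(case.mask.astype(np.uint8), affine), msk_path)
    return img_path, msk_path


def _patient_id_from_path(img_path: Path) -> str:
    name = img_path.name
    if not name.endswith(_IMG_SUFFIX):
        return re.sub(r"\.nii(\.gz)?$", "", name)
    return name[: -len(_IMG_SUFFIX)]


def read_case_nifti(image_path, mask_path, site_id: str | None = None) -> PhantomCase:
    """Load one pair back into a validated :class:`PhantomCase`."""
    image_path = Path(image_path)
    mask_path = Path(mask_path)
    try:
        image = np.asarray(nib.load(image_path).dataobj, dtype=np.float32)
        mask_raw = np.asarray(nib.load(mask_path).dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several format exceptions
        raise FormatError(f"unreadable NIfTI pair {image_path.name}: {exc}") from exc
    if image.ndim != 2 or mask_raw.ndim != 2:
        raise FormatError(
            f"{image_path.name}: expected 2D arrays, got shapes "
            f"{image.shape} / {mask_raw.shape}"
        )
    if image.shape != mask_raw.shape:
        raise FormatError(
            f"{image_path.name}: image shape {image.shape} != mask shape "
            f"{mask_raw.shape}"
        )
    if not np.isin(np.unique(mask_raw), (0, 1)).all():
        raise FormatError(f"{mask_path.name}: mask values outside {{0,1}}")
    patient_id = _patient_id_from_path(image_path)
    case = PhantomCase(
        patient_id=patient_id,
        site_id=site_id if site_id is not None else patient_id.split("_p")[0],
        image=image,
        mask=mask_raw.astype(np.uint8),
    )
    return case.validate()


def load_case_folder(directory, site_id: str | None = None) -> list[PhantomCase]:
    """Load every image/mask pair in a folder; a missing mask, an orphan
    mask, or any malformed pair aborts the load naming the patient."""
    directory = Path(directory)
    if not directory.is_dir():
        raise DataError(f"data folder {directory} does not exist")
    imgs = sorted(directory.glob(f"*{_IMG_SUFFIX}"))
    msks = {p.name: p for p in directory.glob(f"*{_MSK_SUFFIX}")}
    cases = []
    problems = []
    for img_path in imgs:
        pid = _patient_id_from_path(img_path)
        msk_name = pid + _MSK_SUFFIX
        if msk_name not in msks:
            problems.append(f"{pid}: missing mask file")
            continue
        del msks[msk_name]
        try:
            cases.append(read_case_nifti(img_path, directory / msk_name, site_id))
        except (FormatError, DataError) as exc:
            problems.append(f"{pid}: {exc}")
    for orphan in msks:
        problems.append(f"{orphan}: mask without image")
    if problems:
        raise DataError(
            "invalid NIfTI pairs in " + str(directory) + ": " + "; ".join(problems)
        )
    return cases


def write_cohort(cohort: PartitionedCohort, root, force: bool = False) -> Path:
    """Materialise a cohort as ``site_<id>/{train,validation}/...`` folders."""
    root = Path(root)
    for site_id in cohort.sites:
        for split in ("train", "validation"):
            directory = root / f"site_{site_id}" / split
            for case in getattr(cohort, split)[site_id]:
                write_case_nifti(case, directory, force=force)
    return root


def site_data_root(root, site_id: str) -> Path:
    return Path(root) / f"site_{site_id}"
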