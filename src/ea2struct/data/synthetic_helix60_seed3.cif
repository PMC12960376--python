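data_wt_seed3
_entry.id 'wt_seed3'

_cell.entry_id 'wt_seed3'
_cell.length_a 1
_cell.length_b 1
_cell.length_c 1
_cell.angle_alpha 90
_cell.angle_beta 90
_cell.angle_gamma 90

_symmetry.entry_id 'wt_seed3'
_symmetry.space_group_name_H-M ''

loop_
_entity.id
_entity.type
A polymer

loop_
_entity_poly.entity_id
_entity_poly.type
_entity_poly.pdbx_strand_id
_entity_poly.pdbx_seq_one_letter_code
A polypeptide(L) A ?



loop_
_chem_comp.id
_chem_comp.type
ALA .
ARG .
ASN .
ASP .
CYS .
GLN .
GLU .
GLY .
HIS .
ILE .
LEU .
MET .
PHE .
PRO .
SER .
THR .
TRP .
TYR .
VAL .

loop_
_struct_asym.id
_struct_asym.entity_id
Axp A



loop_
_atom_type.symbol
C


loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_formal_charge
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . HIS Axp A . ? 2.60613787 -0.383349755 0.062714827 1 35.57 ? 1 A 1
ATOM 2 C CA . ASN Axp A . ? -0.48455625 2.19716044 1.46766043 1 45.39 ? 2 A 1
ATOM 3 C CA . ASP Axp A . ? -2.46429095 -0.821436186 2.87021804 1 82.08 ? 3 A 1
ATOM 4 C CA . TYR Axp A . ? 1.64844993 -1.95799044 4.44710538 1 67.84 ? 4 A 1
ATOM 5 C CA . LEU Axp A . ? 1.71970911 1.37820455 5.84172742 1 36.12 ? 5 A 1
ATOM 6 C CA . ALA Axp A . ? -1.82052237 1.55070331 7.46421696 1 58.15 ? 6 A 1
ATOM 7 C CA . HIS Axp A . ? -1.00633619 -2.02182875 9.00363893 1 61.14 ? 7 A 1
ATOM 8 C CA . HIS Axp A . ? 2.39316616 -0.704880501 10.4242157 1 40.38 ? 8 A 1
ATOM 9 C CA . PHE Axp A . ? 0.371964962 2.3461366 12.2902632 1 77.75 ? 9 A 1
ATOM 10 C CA . SER Axp A . ? -2.34044305 -0.0365338019 13.650347 1 37.39 ? 10 A 1
ATOM 11 C CA . TYR Axp A . ? 0.266421817 -2.30881587 15.1323808 1 55.43 ? 11 A 1
ATOM 12 C CA . GLN Axp A . ? 2.24834553 0.800373835 16.6005157 1 63.59 ? 12 A 1
ATOM 13 C CA . GLU Axp A . ? -1.57422435 2.14505445 17.8560533 1 57.99 ? 13 A 1
ATOM 14 C CA . ASN Axp A . ? -2.0121952 -1.43694464 19.6050817 1 68.14 ? 14 A 1
ATOM 15 C CA . LEU Axp A . ? 1.6951871 -1.63987238 21.0039187 1 77.96 ? 15 A 1
ATOM 16 C CA . GLN Axp A . ? 1.1420879 2.20269815 22.6121112 1 92.16 ? 16 A 1
ATOM 17 C CA . THR Axp A . ? -2.13222068 0.95339131 23.9691715 1 48.47 ? 17 A 1
ATOM 18 C CA . VAL Axp A . ? -0.538275745 -2.17744909 25.5873808 1 72.16 ? 18 A 1
ATOM 19 C CA . THR Axp A . ? 2.26777566 -0.117421287 27.0343731 1 75.25 ? 19 A 1
ATOM 20 C CA . GLN Axp A . ? -0.77347495 2.36857655 28.5737052 1 49.03 ? 20 A 1
ATOM 21 C CA . LEU Axp A . ? -2.4071216 -0.777443303 29.8553851 1 30.1 ? 21 A 1
ATOM 22 C CA . MET Axp A . ? 1.26358316 -2.29698352 31.3628258 1 93.27 ? 22 A 1
ATOM 23 C CA . GLU Axp A . ? 1.86833922 1.65187166 32.6762992 1 49.4 ? 23 A 1
ATOM 24 C CA . ASN Axp A . ? -1.8366082 1.52761452 34.4086176 1 50.41 ? 24 A 1
ATOM 25 C CA . MET Axp A . ? -0.911403965 -2.17054243 36.0531798 1 87.96 ? 25 A 1
ATOM 26 C CA . GLN Axp A . ? 2.0040322 -0.575751888 37.4967523 1 68.04 ? 26 A 1
ATOM 27 C CA . LEU Axp A . ? 0.343553224 2.00733009 39.2522738 1 60.64 ? 27 A 1
ATOM 28 C CA . HIS Axp A . ? -2.18708321 0.113034576 40.6706822 1 80.26 ? 28 A 1
ATOM 29 C CA . MET Axp A . ? 0.451774795 -2.36094482 41.8799638 1 31.97 ? 29 A 1
ATOM 30 C CA . GLN Axp A . ? 2.04126303 0.992157181 43.2809428 1 75.95 ? 30 A 1
ATOM 31 C CA . GLU Axp A . ? -1.23945543 1.94367184 45.0336929 1 54.33 ? 31 A 1
ATOM 32 C CA . PRO Axp A . ? -1.67559981 -1.66577605 46.240498 1 35.91 ? 32 A 1
ATOM 33 C CA . ILE Axp A . ? 1.76124008 -1.29637693 48.1135587 1 72.93 ? 33 A 1
ATOM 34 C CA . SER Axp A . ? 1.18234762 1.94428508 49.5439851 1 90.55 ? 34 A 1
ATOM 35 C CA . ASN Axp A . ? -2.19779329 0.909227317 50.8808329 1 43.47 ? 35 A 1
ATOM 36 C CA . LEU Axp A . ? -0.379254817 -2.28167485 52.5815039 1 70.96 ? 36 A 1
ATOM 37 C CA . ALA Axp A . ? 2.33369578 0.382505195 54.2247982 1 49.38 ? 37 A 1
ATOM 38 C CA . ALA Axp A . ? -0.174880234 1.95913226 55.4489525 1 78.21 ? 38 A 1
ATOM 39 C CA . PHE Axp A . ? -2.25258462 -0.70673809 56.658146 1 76.94 ? 39 A 1
ATOM 40 C CA . MET Axp A . ? 1.3261748 -1.83181093 58.3046894 1 44.22 ? 40 A 1
ATOM 41 C CA . LEU Axp A . ? 1.61511994 1.3582357 60.0064944 1 83.94 ? 41 A 1
ATOM 42 C CA . VAL Axp A . ? -1.66575656 1.78559441 61.4703832 1 72.75 ? 42 A 1
ATOM 43 C CA . ASP Axp A . ? -1.03487462 -1.96854576 63.2639889 1 74.38 ? 43 A 1
ATOM 44 C CA . PRO Axp A . ? 2.27261671 -0.581363762 64.3383487 1 83.3 ? 44 A 1
ATOM 45 C CA . ILE Axp A . ? 0.370554702 2.14299197 66.2257421 1 57.86 ? 45 A 1
ATOM 46 C CA . PRO Axp A . ? -2.20135401 -0.0457716639 67.4321298 1 79.32 ? 46 A 1
ATOM 47 C CA . CYS Axp A . ? 0.47209054 -2.37028216 68.8604117 1 87.1 ? 47 A 1
ATOM 48 C CA . ILE Axp A . ? 2.2334842 1.15611613 70.46308 1 36.65 ? 48 A 1
ATOM 49 C CA . ASP Axp A . ? -1.23337987 1.8161849 71.7997484 1 85.23 ? 49 A 1
ATOM 50 C CA . ILE Axp A . ? -1.68315473 -1.35079105 73.5013762 1 55.61 ? 50 A 1
ATOM 51 C CA . GLU Axp A . ? 1.81178862 -1.46102402 75.0207982 1 61.18 ? 51 A 1
ATOM 52 C CA . ARG Axp A . ? 0.921076142 1.92314069 76.5167219 1 39.51 ? 52 A 1
ATOM 53 C CA . GLN Axp A . ? -2.27876804 0.715181868 77.877132 1 75.4 ? 53 A 1
ATOM 54 C CA . CYS Axp A . ? -0.44941531 -2.13709159 79.4390129 1 48.98 ? 54 A 1
ATOM 55 C CA . GLY Axp A . ? 2.2769194 0.122057754 81.0967155 1 86.62 ? 55 A 1
ATOM 56 C CA . VAL Axp A . ? -0.145109675 1.95148507 82.6285288 1 47.9 ? 56 A 1
ATOM 57 C CA . TRP Axp A . ? -2.23363564 -0.766442557 84.1256579 1 66.52 ? 57 A 1
ATOM 58 C CA . VAL Axp A . ? 1.31248797 -1.83595583 85.523266 1 55.98 ? 58 A 1
ATOM 59 C CA . ASP Axp A . ? 2.00335162 1.43596537 86.9788527 1 69.84 ? 59 A 1
ATOM 60 C CA . TYR Axp A . ? -1.64199954 1.39570564 88.8241359 1 42.78 ? 60 A 1
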