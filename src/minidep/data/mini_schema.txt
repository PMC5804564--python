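# minidep packaged dictionary schema (flat dialect).
#
# Grammar: one record per non-comment line, fields separated by ';':
#   schema; version=V
#   category; name=NAME; keys=item|item        (key names relative to NAME)
#   item; name=NAME; type={text,int,float,enum,date}; mandatory={yes,no}
#         [; enum=a|b|c] [; hard=lo:hi] [; soft=lo:hi] [; parent=category.item]
# Item records belong to the most recent category record.  Ranges are
# inclusive; soft limits mark statistically unusual values (warning), hard
# limits physically impossible ones (error).
schema; version=1.0

category; name=entity; keys=id
item; name=id; type=int; mandatory=yes
item; name=type; type=enum; mandatory=yes; enum=polymer|non-polymer|water
item; name=pdbx_description; type=text; mandatory=no

category; name=entity_poly; keys=entity_id
item; name=entity_id; type=int; mandatory=yes; parent=entity.id
item; name=type; type=enum; mandatory=no; enum=polypeptide(L)|polyribonucleotide|polydeoxyribonucleotide
item; name=pdbx_seq_one_letter_code; type=text; mandatory=yes
item; name=pdbx_strand_id; type=text; mandatory=no

category; name=entity_src_gen; keys=entity_id
item; name=entity_id; type=int; mandatory=yes; parent=entity.id
item; name=pdbx_gene_src_scientific_name; type=text; mandatory=no
item; name=gene_src_common_name; type=text; mandatory=no
item; name=pdbx_gene_src_ncbi_taxonomy_id; type=int; mandatory=no
item; name=gene_src_strain; type=text; mandatory=no
item; name=pdbx_host_org_scientific_name; type=text; mandatory=no
item; name=pdbx_host_org_ncbi_taxonomy_id; type=int; mandatory=no
item; name=pdbx_host_org_vector_type; type=enum; mandatory=no; enum=plasmid|virus|cosmid|baculovirus|phage|phagemid
item; name=plasmid_name; type=text; mandatory=no

category; name=atom_site; keys=id
item; name=group_PDB; type=enum; mandatory=yes; enum=ATOM|HETATM
item; name=id; type=int; mandatory=yes
item; name=type_symbol; type=text; mandatory=yes
item; name=label_atom_id; type=text; mandatory=yes
item; name=label_alt_id; type=text; mandatory=no
item; name=label_comp_id; type=text; mandatory=yes
item; name=label_asym_id; type=text; mandatory=yes
item; name=label_entity_id; type=int; mandatory=no; parent=entity.id
item; name=label_seq_id; type=int; mandatory=yes
item; name=Cartn_x; type=float; mandatory=yes; hard=-9999:9999
item; name=Cartn_y; type=float; mandatory=yes; hard=-9999:9999
item; name=Cartn_z; type=float; mandatory=yes; hard=-9999:9999
item; name=occupancy; type=float; mandatory=yes; hard=0:1
item; name=B_iso_or_equiv; type=float; mandatory=yes; hard=0:1000; soft=1:150

category; name=cell; keys=entry_id
item; name=entry_id; type=text; mandatory=yes
item; name=length_a; type=float; mandatory=yes; hard=1:10000
item; name=length_b; type=float; mandatory=yes; hard=1:10000
item; name=length_c; type=float; mandatory=yes; hard=1:10000
item; name=angle_alpha; type=float; mandatory=yes; hard=0.01:179.99
item; name=angle_beta; type=float; mandatory=yes; hard=0.01:179.99
item; name=angle_gamma; type=float; mandatory=yes; hard=0.01:179.99

category; name=symmetry; keys=entry_id
item; name=entry_id; type=text; mandatory=yes
item; name=space_group_name_H-M; type=text; mandatory=yes
item; name=Int_Tables_number; type=int; mandatory=no; hard=1:230

category; name=reflns; keys=entry_id
item; name=entry_id; type=text; mandatory=yes
item; name=pdbx_Rmerge_I_obs; type=float; mandatory=no; hard=0:100; soft=0.01:0.2
item; name=d_resolution_high; type=float; mandatory=no; hard=0.1:100
item; name=pdbx_redundancy; type=float; mandatory=no; hard=1:1000
item; name=pdbx_wavelength; type=float; mandatory=no; hard=0.1:10
item; name=pdbx_sf_wavelength; type=float; mandatory=no; hard=0.1:10
item; name=pdbx_free_R_flag; type=enum; mandatory=no; enum=yes|no
item; name=pdbx_aniso_B; type=enum; mandatory=no; enum=yes|no
item; name=pdbx_sf_complete; type=enum; mandatory=no; enum=yes|no
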