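species_id,latin_name,guild,RG,RM,RC,RD
alopecurus_japonicus,Alopecurus japonicus,grass,3,2,2,2
beckmannia_syzigachne,Beckmannia syzigachne,grass,3,3,3,3
cynodon_dactylon,Cynodon dactylon,grass,0,2,1,0
digitaria_sanguinalis,Digitaria sanguinalis,grass,1,3,3,1
eleusine_indica,Eleusine indica,grass,0,3,1,2
leptochloa_chinensis,Leptochloa chinensis,grass,3,3,3,3
sclerochloa_dura,Sclerochloa dura,grass,1,1,0,0
alopecurus_aequalis,Alopecurus aequalis,grass,3,2,3,3
echinochloa_crusgalli,Echinochloa crusgalli,grass,3,3,3,3
panicum_bisulcatum,Panicum bisulcatum,grass,0,2,1,1
polypogon_fugax,Polypogon fugax,grass,1,3,3,2
setaria_viridis,Setaria viridis,grass,1,3,1,1
cyperus_difformis,Cyperus difformis,sedge,3,3,3,3
cyperus_iria,Cyperus iria,sedge,3,3,3,3
fimbristylis_miliacea,Fimbristylis miliacea,sedge,1,2,1,0
heleocharis_yokoscensis,Heleocharis yokoscensis,sedge,0,3,3,3
juncellus_serotinus,Juncellus serotinus,sedge,0,0,1,0
kyllinga_brevifolia,Kyllinga brevifolia,sedge,0,0,0,1
scirpus_juncoides,Scirpus juncoides,sedge,2,2,3,2
scirpus_triangulatus,Scirpus triangulatus,sedge,3,2,3,3
scirpus_wallichii,Scirpus wallichii,sedge,0,1,3,3
scirpus_yagara,Scirpus yagara,sedge,1,1,0,2
ajuga_ciliate,Ajuga ciliate,broadleaf,0,1,0,0
najas_foveolate,Najas foveolate,broadleaf,0,2,0,0
najas_minor,Najas minor,broadleaf,3,3,3,3
acalypha_australis,Acalypha australis,broadleaf,1,0,0,1
astragalus_sinicus,Astragalus sinicus,broadleaf,2,0,0,0
glycine_soja,Glycine soja,broadleaf,1,0,0,0
medicago_polymorpha,Medicago polymorpha,broadleaf,1,0,1,0
vicia_gigantea,Vicia gigantea,broadleaf,1,0,1,0
vicia_hirsuta,Vicia hirsuta,broadleaf,2,0,0,0
aeschynomene_indica,Aeschynomene indica,broadleaf,1,0,1,0
carpesium_abrotanoides,Carpesium abrotanoides,broadleaf,0,2,0,0
eclipta_prostrata,Eclipta prostrata,broadleaf,2,2,1,0
lapsana_apogonoides,Lapsana apogonoides,broadleaf,3,3,1,1
hemistepta_lyrate,Hemistepta lyrate,broadleaf,1,3,3,3
chenopodium_album,Chenopodium album,broadleaf,1,3,3,3
polygonum_aviculare,Polygonum aviculare,broadleaf,2,3,3,0
polygonum_lapathifolium,Polygonum lapathifolium,broadleaf,2,3,2,2
polygonum_nepalense,Polygonum nepalense,broadleaf,0,1,1,0
polygonum_posumbu,Polygonum posumbu,broadleaf,0,3,0,0
polygonum_viscosum,Polygonum viscosum,broadleaf,2,2,0,0
rumex_dentatus,Rumex dentatus,broadleaf,0,3,2,0
ludwigia_prostrata,Ludwigia prostrata,broadleaf,3,3,3,3
geranium_carolinianum,Geranium carolinianum,broadleaf,1,0,1,0
clematis_hexapetala,Clematis hexapetala,broadleaf,3,3,3,2
ammannia_baccifera,Ammannia baccifera,broadleaf,3,3,3,3
ammannia_multiflora,Ammannia multiflora,broadleaf,3,2,2,3
rotala_indica,Rotala indica,broadleaf,3,3,3,3
galium_aparine,Galium aparine,broadleaf,1,1,2,3
cnidium_monnieri,Cnidium monnieri,broadleaf,1,0,0,0
capsella_bursa_pastoris,Capsella bursa-pastoris,broadleaf,3,2,0,2
rorippa_indica,Rorippa indica,broadleaf,1,1,2,1
myosoton_aquaticum,Myosoton aquaticum,broadleaf,3,3,3,3
lindernia_procumbens,Lindernia procumbens,broadleaf,3,3,3,3
mazus_japonicus,Mazus japonicus,broadleaf,3,3,3,3
veronica_peregrina,Veronica peregrina,broadleaf,1,1,0,3
veronica_undulata,Veronica undulata,broadleaf,0,1,0,2
monochoria_vaginalis,Monochoria vaginalis,broadleaf,3,3,3,3
alisma_plantago_aquatica,Alisma plantago-aquatica,broadleaf,0,1,1,2
trigonotis_peduncularis,Trigonotis peduncularis,broadleaf,0,0,1,1
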