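api_name,category,note
altrenogest,authorisation_change,new formulation authorised 2018
asenapine,authorisation_change,sole product deregistered 2017
carglumic acid,authorisation_change,second product authorised June 2017
cefalotin,supply_shortage,national shortage recorded 2019
cladribine,authorisation_change,authorised August 2017
cobimetinib,authorisation_change,authorised November 2015
cyclizine,unexplained,cause of change unknown
dacarbazine,authorisation_change,authorised March 2017
dasabuvir,authorisation_change,combination application withdrawn 2016
edoxaban,authorisation_change,authorised June 2015
eluxadoline,authorisation_change,authorised 2017; withdrawn from market 2019
fomepizole,unexplained,cause of change unknown
gadobenic acid,unexplained,cause of change unknown
gadodiamide,authorisation_change,deregistered 2018
glecaprevir,authorisation_change,combination authorised July 2017
ixazomib,authorisation_change,authorised November 2016
nitrofurantoin,supply_shortage,shortage recorded 2018-2021
nystatin,unexplained,cause of change unknown
ombitasvir,authorisation_change,combination application withdrawn 2016
osimertinib,authorisation_change,authorised February 2016
palbociclib,authorisation_change,authorised November 2016
paritaprevir,authorisation_change,combination application withdrawn 2016
pibrentasvir,authorisation_change,combination authorised July 2017
prednisone,supply_shortage,shortage recorded 2019
safinamide,authorisation_change,authorised February 2015
toceranib,authorisation_change,deregistered 2019
tofacitinib,authorisation_change,authorised March 2017
velpatasvir,authorisation_change,combinations authorised July 2016
venetoclax,authorisation_change,authorised December 2016
vinflunine,unexplained,cause of change unknown
voxilaprevir,authorisation_change,combination authorised July 2016
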