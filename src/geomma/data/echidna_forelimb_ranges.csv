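specimen,side,joint,dof,kind,units,min,max
E44,L,scapulocoracoid,medial-lateral rotation,rotation,deg,21,28
E46,L,scapulocoracoid,medial-lateral rotation,rotation,deg,14,18
E46,R,scapulocoracoid,medial-lateral rotation,rotation,deg,23,28
E48,L,scapulocoracoid,medial-lateral rotation,rotation,deg,27,31
E48,R,scapulocoracoid,medial-lateral rotation,rotation,deg,20,28
E44,L,glenohumeral,abduction-adduction,rotation,deg,-57,37
E46,L,glenohumeral,abduction-adduction,rotation,deg,-35,23
E46,R,glenohumeral,abduction-adduction,rotation,deg,0,44
E48,L,glenohumeral,abduction-adduction,rotation,deg,-13,42
E48,R,glenohumeral,abduction-adduction,rotation,deg,-9,44
E44,L,glenohumeral,long-axis rotation,rotation,deg,-41,26
E46,L,glenohumeral,long-axis rotation,rotation,deg,-41,13
E46,R,glenohumeral,long-axis rotation,rotation,deg,-27,36
E48,L,glenohumeral,long-axis rotation,rotation,deg,-3,38
E48,R,glenohumeral,long-axis rotation,rotation,deg,-17,38
E44,L,glenohumeral,flexion-extension,rotation,deg,-31,24
E46,L,glenohumeral,flexion-extension,rotation,deg,-17,37
E46,R,glenohumeral,flexion-extension,rotation,deg,7,41
E48,L,glenohumeral,flexion-extension,rotation,deg,-1,36
E48,R,glenohumeral,flexion-extension,rotation,deg,-1,33
E44,L,glenohumeral,craniocaudal translation,translation,mm,-5.9,4.5
E46,L,glenohumeral,craniocaudal translation,translation,mm,-4.5,4.3
E46,R,glenohumeral,craniocaudal translation,translation,mm,-5.4,1.7
E48,L,glenohumeral,craniocaudal translation,translation,mm,-2.6,2.7
E48,R,glenohumeral,craniocaudal translation,translation,mm,-2.5,3.6
E44,L,glenohumeral,proximodistal translation,translation,mm,-0.4,2.7
E46,L,glenohumeral,proximodistal translation,translation,mm,-0.9,2.4
E46,R,glenohumeral,proximodistal translation,translation,mm,-0.9,2.6
E48,L,glenohumeral,proximodistal translation,translation,mm,0.1,2.6
E48,R,glenohumeral,proximodistal translation,translation,mm,0.5,2.5
E44,L,glenohumeral,dorsoventral translation,translation,mm,-3.8,0.1
E46,L,glenohumeral,dorsoventral translation,translation,mm,-3.2,0.4
E46,R,glenohumeral,dorsoventral translation,translation,mm,0.6,3.0
E48,L,glenohumeral,dorsoventral translation,translation,mm,-2.9,0.4
E48,R,glenohumeral,dorsoventral translation,translation,mm,0.3,2.7
E44,L,humeroradioulnar,abduction-adduction,rotation,deg,-31,8
E46,L,humeroradioulnar,abduction-adduction,rotation,deg,-34,8
E46,R,humeroradioulnar,abduction-adduction,rotation,deg,-14,26
E48,L,humeroradioulnar,abduction-adduction,rotation,deg,-59,8
E48,R,humeroradioulnar,abduction-adduction,rotation,deg,-38,13
E44,L,humeroradioulnar,long-axis rotation,rotation,deg,7,50
E46,L,humeroradioulnar,long-axis rotation,rotation,deg,1,54
E46,R,humeroradioulnar,long-axis rotation,rotation,deg,8,48
E48,L,humeroradioulnar,long-axis rotation,rotation,deg,-3,69
E48,R,humeroradioulnar,long-axis rotation,rotation,deg,-2,67
E44,L,humeroradioulnar,flexion-extension,rotation,deg,-15,38
E46,L,humeroradioulnar,flexion-extension,rotation,deg,-32,39
E46,R,humeroradioulnar,flexion-extension,rotation,deg,-15,40
E48,L,humeroradioulnar,flexion-extension,rotation,deg,-38,30
E48,R,humeroradioulnar,flexion-extension,rotation,deg,-16,50
E44,L,humeroradioulnar,craniocaudal translation,translation,mm,-1.5,1.6
E46,L,humeroradioulnar,craniocaudal translation,translation,mm,-1.0,1.8
E46,R,humeroradioulnar,craniocaudal translation,translation,mm,-1.2,1.0
E48,L,humeroradioulnar,craniocaudal translation,translation,mm,-2.4,0.5
E48,R,humeroradioulnar,craniocaudal translation,translation,mm,-1.7,1.3
E44,L,humeroradioulnar,proximodistal translation,translation,mm,-1.2,0.2
E46,L,humeroradioulnar,proximodistal translation,translation,mm,-1.9,0.4
E46,R,humeroradioulnar,proximodistal translation,translation,mm,-2.0,1.6
E48,L,humeroradioulnar,proximodistal translation,translation,mm,-1.9,1.5
E48,R,humeroradioulnar,proximodistal translation,translation,mm,-1.9,0.4
E44,L,humeroradioulnar,prepostaxial translation,translation,mm,-2.3,1.5
E46,L,humeroradioulnar,prepostaxial translation,translation,mm,-1.9,2.6
E46,R,humeroradioulnar,prepostaxial translation,translation,mm,-0.9,3.0
E48,L,humeroradioulnar,prepostaxial translation,translation,mm,-3.6,1.5
E48,R,humeroradioulnar,prepostaxial translation,translation,mm,-1.3,4.0
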